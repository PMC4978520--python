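"""Stimulation and measurement protocols.

Stimulus strength is dimensionless: every afferent on a side receives the
same absolute current ``strength * I_unit`` (nA) for the duration of the
drive, where ``I_unit`` is the threshold current of the smallest afferent,
so strength 1.0 recruits exactly that cell.  Because channel densities are
fixed while total conductance grows with membrane area, larger afferents
need more absolute current, and the number of recruited afferents rises
monotonically with strength.

The drive waveform is a constant-current step (default 5 ms, onset 5 ms).
Calibration protocols (current-step families, synchronous-shock EPSP,
single-FF-spike IPSP series) isolate the relevant subcircuit by zeroing the
conductances of the couplings that are not part of the measurement —
zeroing a gap junction also removes its standing conductance load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import CircuitSpec
from .errors import ConfigurationError
from .neurodynamics import (
    BatchResult,
    NetworkEngine,
    TrialRecording,
    hh_threshold_current,
)

__all__ = [
    "ProtocolSpec",
    "StimulusGrid",
    "StepFamily",
    "IpspExperiment",
    "SweepResult",
    "afferent_thresholds",
    "unit_current",
    "strength_full",
    "recruit_afferents",
    "predicted_recruited_count",
    "drive_protocol",
    "passive_steps",
    "measure_epsp",
    "measure_ipsp",
    "peak_conductance_ratio",
    "stimulus_grid",
    "run_grid",
    "run_unilateral",
    "check_ff_recruitment",
]

#: Default afferent drive timing (ms): onset after a silent baseline, and a
#: constant-current step long enough to cover the 5-15 ms escape-latency
#: range the model is calibrated against (an M-cell with ~4 ms effective
#: time constant cannot express that latency range under a drive shorter
#: than the latencies themselves).
DRIVE_ONSET = 5.0
DRIVE_DURATION = 20.0


@dataclass(frozen=True)
class ProtocolSpec:
    """One trial's stimulation: afferent drive, injections, forced spikes.

    ``aud_currents`` maps a side to the absolute current (nA) injected into
    every afferent on that side during ``aud_window``; ``injections`` are
    ``(population, side, cell_id, amplitude_nA, t_on, t_off)`` current steps
    into LIF cells; ``forced_spikes`` are ``(population, side, cell_id,
    t_ms)`` direct spike injections.
    """

    kind: str  # 'current_step' | 'afferent_drive' | 'synchronous_shock' | 'ff_single_spike'
    aud_currents: dict = field(default_factory=dict)
    aud_window: tuple[float, float] = (DRIVE_ONSET, DRIVE_ONSET + DRIVE_DURATION)
    injections: tuple = ()
    forced_spikes: tuple = ()
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if any(a < 0 for a in self.aud_currents.values()):
            raise ConfigurationError("afferent drive currents must be >= 0")

    def describe(self) -> dict:
        return {
            "kind": self.kind,
            "aud_currents_nA": dict(self.aud_currents),
            "aud_window_ms": list(self.aud_window),
            "n_injections": len(self.injections),
            "n_forced_spikes": len(self.forced_spikes),
            **self.metadata,
        }


@dataclass(frozen=True)
class StimulusGrid:
    """Cartesian grid of (left strength, right strength) drive conditions."""

    strengths_left: np.ndarray
    strengths_right: np.ndarray
    onset: float = DRIVE_ONSET
    duration: float = DRIVE_DURATION
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.strengths_left), len(self.strengths_right))


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

_threshold_cache: dict[tuple, np.ndarray] = {}


def afferent_thresholds(circuit: CircuitSpec, *,
                        window: float | None = None) -> np.ndarray:
    """Threshold current (nA) per afferent area, ascending with area.

    ``window`` is the spike-detection window of the probe; it defaults to
    the drive duration so that 'recruited at strength s' and 'spikes during
    the drive' coincide.
    """
    pop = circuit.population("auditory", "left")
    window = DRIVE_DURATION if window is None else window
    key = (pop.params.kinetics_key(), pop.params.surface_areas, window,
           circuit.dt)
    if key not in _threshold_cache:
        areas = np.asarray(pop.params.surface_areas)
        _threshold_cache[key] = hh_threshold_current(
            pop.params, areas, t_window=window, dt=circuit.dt)
    return _threshold_cache[key]


def unit_current(circuit: CircuitSpec) -> float:
    """Drive current (nA) per unit strength: threshold of the smallest cell."""
    return float(afferent_thresholds(circuit)[0])


def strength_full(circuit: CircuitSpec) -> float:
    """Strength at which every afferent on a driven side is recruited."""
    th = afferent_thresholds(circuit)
    return float(th[-1] / th[0])


def recruit_afferents(circuit: CircuitSpec, strength: float,
                      side: str) -> np.ndarray:
    """Per-afferent absolute current assignment (nA) for one side.

    Every afferent receives the same current ``strength * I_unit``;
    recruitment order is then set by the area-dependent thresholds.
    """
    if strength < 0:
        raise ConfigurationError("stimulus strength must be >= 0")
    pop = circuit.population("auditory", side)
    return np.full(pop.n, strength * unit_current(circuit))


def predicted_recruited_count(circuit: CircuitSpec,
                              strength: float | np.ndarray) -> np.ndarray | int:
    """Afferents recruited at ``strength``, from the threshold table."""
    th = afferent_thresholds(circuit)
    s = np.atleast_1d(np.asarray(strength, dtype=float))
    count = (th[None, :] <= s[..., None] * th[0] * (1 + 1e-12)).sum(axis=-1)
    if np.ndim(strength) == 0:
        return int(count[0])
    return count


def drive_protocol(circuit: CircuitSpec, left_strength: float,
                   right_strength: float, *, onset: float = DRIVE_ONSET,
                   duration: float = DRIVE_DURATION) -> ProtocolSpec:
    """Bilateral afferent-drive protocol at the given strengths."""
    iu = unit_current(circuit)
    currents = {}
    for side, s in (("left", left_strength), ("right", right_strength)):
        if s < 0:
            raise ConfigurationError("stimulus strength must be >= 0")
        currents[side] = s * iu
    return ProtocolSpec(
        kind="afferent_drive", aud_currents=currents,
        aud_window=(onset, onset + duration),
        metadata={"left_strength": left_strength,
                  "right_strength": right_strength})


# ---------------------------------------------------------------------------
# passive current-step families
# ---------------------------------------------------------------------------


@dataclass
class StepFamily:
    """Voltage responses of one isolated cell to a family of current steps."""

    population: str
    side: str
    currents: np.ndarray  # nA
    t: np.ndarray  # ms
    traces: np.ndarray  # (n_currents, n_samples) mV
    onset: float
    offset: float
    dt: float

    def deflection(self, i: int) -> float:
        """Steady-state voltage deflection (mV) of step ``i``."""
        pre = self.t < self.onset
        tail = (self.t > self.offset - 0.05 * (self.offset - self.onset)) & (
            self.t <= self.offset)
        return float(self.traces[i][tail].mean() - self.traces[i][pre].mean())

    def relaxation(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(t, V) of the post-step relaxation, t rebased to the step offset."""
        sel = self.t >= self.offset
        return self.t[sel] - self.offset, self.traces[i][sel]


def passive_steps(circuit: CircuitSpec, population: str, side: str,
                  currents, *, cell: int = 0, onset: float | None = None,
                  duration: float | None = None,
                  post: float | None = None) -> StepFamily:
    """Current-step family on one cell, isolated from all coupling.

    Step duration defaults to 6 membrane time constants so the deflection is
    at steady state; the recording continues for the same span after offset
    for relaxation fits.
    """
    params = circuit.population(population, side).params
    tau = params.tau_m
    onset = 2.0 if onset is None else onset
    duration = 10.0 * tau if duration is None else duration
    post = 6.0 * tau if post is None else post
    # LIF-only rebuild (the afferents play no role once isolated) keeps the
    # long step families cheap
    import copy as _copy

    from .circuit import build_circuit

    cfg = _copy.deepcopy(circuit.config)
    cfg["hh"]["auditory"]["n_per_side"] = 0
    iso = build_circuit(circuit.variant, config=cfg).isolated()
    engine = NetworkEngine(iso)
    currents = np.atleast_1d(np.asarray(currents, dtype=float))
    traces = []
    t = None
    for amp in currents:
        proto = ProtocolSpec(
            kind="current_step",
            injections=((population, side, cell, float(amp), onset,
                         onset + duration),),
            metadata={"amplitude_nA": float(amp)})
        rec = engine.run(proto, t_end=onset + duration + post)
        traces.append(rec.v(population, side, cell))
        t = rec.t
    return StepFamily(population=population, side=side, currents=currents,
                      t=t, traces=np.vstack(traces), onset=onset,
                      offset=onset + duration, dt=engine.dt)


# ---------------------------------------------------------------------------
# EPSP / IPSP calibration protocols
# ---------------------------------------------------------------------------


def _aud_group_names(circuit: CircuitSpec) -> list[str]:
    return [n for n in circuit.group_names() if n.startswith("auditory.")]


def _ff_group_names(circuit: CircuitSpec) -> list[str]:
    out = []
    for s in circuit.synapses:
        if s.pre_pop[0] == "FF" or s.post_pop[0] == "FF":
            out.append(s.name)
    for g in circuit.gap_junctions:
        if g.post_pop[0] == "FF":
            out.append(g.name)
    return out


def measure_epsp(circuit: CircuitSpec, *, side: str = "left",
                 disable_ff: bool = True, zero_glutamate: bool = False,
                 zero_gap: bool = False, shock_time: float = 5.0,
                 t_end: float = 25.0) -> TrialRecording:
    """Compound M-cell EPSP from synchronous activation of one side's afferents.

    All afferents on ``side`` are driven with a strong brief current pulse so
    they fire one near-synchronous spike; the M-cell response mixes the
    instantaneous gap-junction component and the delayed glutamatergic one,
    separable via the recorded conductance traces or the ``zero_*`` switches.
    FF-related couplings are disabled by default to isolate the EPSP.
    """
    zero = []
    if disable_ff:
        zero += _ff_group_names(circuit)
    if zero_glutamate:
        zero += [s.name for s in circuit.synapses
                 if s.transmitter == "glutamate"]
    if zero_gap:
        zero += [g.name for g in circuit.gap_junctions
                 if g.post_pop[0] == "M"]
    sub = circuit.with_zeroed_groups(set(zero))
    amp = 10.0 * float(afferent_thresholds(circuit, window=20.0)[-1])
    proto = ProtocolSpec(
        kind="synchronous_shock",
        aud_currents={side: amp}, aud_window=(shock_time, shock_time + 1.5),
        metadata={"shock_side": side, "shock_amp_nA": amp})
    rec = NetworkEngine(sub).run(proto, t_end=t_end, record_g=True)
    rec.metadata["shock_time_ms"] = shock_time
    return rec


@dataclass
class IpspExperiment:
    """Single-FF-spike IPSPs in the M-cells across holding currents.

    ``recordings`` maps each holding current (nA, injected into both M-cells)
    to the corresponding trial; trials whose holding current drives the cell
    above spike threshold are flagged (``flagged``) rather than dropped.
    """

    recordings: dict[float, TrialRecording]
    side: str
    ff_cell: int
    spike_time: float
    arrival_time: float
    flagged: tuple[float, ...] = ()

    @property
    def ipsi_key(self) -> tuple[str, str]:
        return ("M", self.side)

    @property
    def contra_key(self) -> tuple[str, str]:
        return ("M", "right" if self.side == "left" else "left")


def measure_ipsp(circuit: CircuitSpec, holding_currents, *,
                 side: str = "left", ff_cell: int = 0,
                 spike_time: float = 10.0,
                 t_end: float = 35.0) -> IpspExperiment:
    """IPSPs in the M-cells from one forced FF spike, per holding current.

    The afferent couplings are zeroed (the measurement needs only the FF ->
    M glycinergic synapses); each M-cell is held with a constant current
    from trial start, pre-settled at the corresponding steady state, and the
    FF cell is made to fire exactly one spike by direct spike injection.
    The IPSP amplitude flips sign where the holding potential crosses the
    glycine reversal.
    """
    sub = circuit.with_zeroed_groups(_aud_group_names(circuit))
    delay = min((s.delay for s in circuit.synapses
                 if s.pre_pop == ("FF", side) and s.post_pop[0] == "M"),
                default=0.0)
    engine = NetworkEngine(sub)
    recordings: dict[float, TrialRecording] = {}
    flagged = []
    for amp in np.atleast_1d(np.asarray(holding_currents, dtype=float)):
        inj = tuple(
            ("M", s, 0, float(amp), 0.0, t_end) for s in ("left", "right")
            if ("M", s) in sub.populations and sub.populations[("M", s)].n)
        proto = ProtocolSpec(
            kind="ff_single_spike", injections=inj,
            forced_spikes=(("FF", side, ff_cell, spike_time),),
            metadata={"holding_nA": float(amp)})
        rec = engine.run(proto, t_end=t_end, record_g=True)
        recordings[float(amp)] = rec
        if rec.metadata.get("suprathreshold_hold"):
            flagged.append(float(amp))
    return IpspExperiment(
        recordings=recordings, side=side, ff_cell=ff_cell,
        spike_time=spike_time, arrival_time=spike_time + delay,
        flagged=tuple(flagged))


def peak_conductance_ratio(exp: IpspExperiment) -> float:
    """Peak contra/ipsi glycinergic conductance ratio at the two M-cells."""
    rec = next(iter(exp.recordings.values()))
    ipsi_name = f"FF.{exp.side}->M.{exp.side}:glycine"
    contra_side = "right" if exp.side == "left" else "left"
    contra_name = f"FF.{exp.side}->M.{contra_side}:glycine"
    if ipsi_name not in rec.conductances or contra_name not in rec.conductances:
        raise ConfigurationError(
            "circuit lacks ipsi and/or contra FF->M glycinergic groups")
    return float(rec.conductances[contra_name].max()
                 / rec.conductances[ipsi_name].max())


# ---------------------------------------------------------------------------
# stimulus-grid sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """M-cell spike bookkeeping over a stimulus grid.

    ``m_first_left[i, j]`` is the first spike time (ms, NaN if silent) of
    the left M-cell at left strength ``i`` and right strength ``j``.
    """

    grid: StimulusGrid
    m_first_left: np.ndarray
    m_first_right: np.ndarray
    recruited_left: np.ndarray
    recruited_right: np.ndarray
    batch: BatchResult
    metadata: dict = field(default_factory=dict)


def stimulus_grid(circuit: CircuitSpec, n: int = 41,
                  s_max: float | None = None, *, onset: float = DRIVE_ONSET,
                  duration: float = DRIVE_DURATION) -> StimulusGrid:
    """Default sweep grid: strengths 0 .. 4 x the full-recruitment strength.

    Beyond full recruitment, stimulus strength keeps modulating afferent
    firing rates (intensity coding), and the short-latency response regime
    of the M-cells lies in that range; the grid spans both regimes.
    """
    if s_max is None:
        s_max = 4.0 * strength_full(circuit)
    s = np.linspace(0.0, s_max, n)
    return StimulusGrid(strengths_left=s, strengths_right=s.copy(),
                        onset=onset, duration=duration,
                        metadata={"s_max": s_max})


def run_grid(circuit: CircuitSpec, grid: StimulusGrid | None = None, *,
             t_end: float = 55.0,
             engine: NetworkEngine | None = None) -> SweepResult:
    """Simulate every (left, right) strength combination of a grid."""
    if grid is None:
        grid = stimulus_grid(circuit)
    iu = unit_current(circuit)
    sL, sR = np.meshgrid(grid.strengths_left, grid.strengths_right,
                         indexing="ij")
    if engine is None:
        engine = NetworkEngine(circuit)
    batch = engine.run_batch(
        sL.ravel() * iu, sR.ravel() * iu,
        t_on=grid.onset, t_off=grid.onset + grid.duration, t_end=t_end)
    shape = grid.shape

    def _first(key):
        if key in batch.first_spike and batch.first_spike[key].shape[1]:
            return batch.first_spike[key][:, 0].reshape(shape)
        return np.full(shape, np.nan)

    def _recruited(key):
        if key in batch.n_spikes:
            return (batch.n_spikes[key] > 0).sum(axis=1).reshape(shape)
        return np.zeros(shape, dtype=int)

    return SweepResult(
        grid=grid,
        m_first_left=_first(("M", "left")),
        m_first_right=_first(("M", "right")),
        recruited_left=_recruited(("auditory", "left")),
        recruited_right=_recruited(("auditory", "right")),
        batch=batch,
        metadata={"t_end": t_end, "unit_current_nA": iu,
                  "variant": circuit.variant.value})


def run_unilateral(circuit: CircuitSpec, strengths, side: str = "left", *,
                   onset: float = DRIVE_ONSET, duration: float = DRIVE_DURATION,
                   t_end: float = 55.0) -> dict:
    """Unilateral drive at a vector of strengths; returns M latencies (ms).

    Latencies are measured from drive onset for the M-cell on the stimulated
    side (NaN where it stays silent).
    """
    strengths = np.asarray(strengths, dtype=float)
    if (strengths < 0).any():
        raise ConfigurationError("stimulus strength must be >= 0")
    iu = unit_current(circuit)
    amps = strengths * iu
    zeros = np.zeros_like(amps)
    engine = NetworkEngine(circuit)
    batch = engine.run_batch(
        amps if side == "left" else zeros,
        amps if side == "right" else zeros,
        t_on=onset, t_off=onset + duration, t_end=t_end)
    lat = batch.m_first(side) - onset
    return {"strengths": strengths, "latency_ms": lat, "side": side,
            "batch": batch, "onset": onset}


def check_ff_recruitment(circuit: CircuitSpec) -> dict:
    """Verify a single afferent spike fires its paired FF cell.

    Drives the circuit at strength 1.0 (recruiting exactly the smallest
    afferent) with all glycinergic inhibition zeroed and checks the paired
    FF cell spikes, per the tuning rule that the afferent->FF electrical
    coupling is just sufficient to recruit the FF pool without inhibition.
    Raises :class:`ConfigurationError` if the FF cell stays silent.
    """
    sub = circuit.with_zeroed_groups(
        [s.name for s in circuit.synapses if s.transmitter == "glycine"])
    iu = unit_current(circuit)
    engine = NetworkEngine(sub)
    batch = engine.run_batch(
        np.array([iu]), np.array([0.0]),
        t_on=DRIVE_ONSET, t_off=DRIVE_ONSET + DRIVE_DURATION, t_end=30.0)
    aud_spiked = batch.n_spikes[("auditory", "left")][0] > 0
    ff_spiked = batch.n_spikes[("FF", "left")][0] > 0
    n_recruited = int(aud_spiked.sum())
    if not aud_spiked[0]:
        raise ConfigurationError(
            "unit-strength drive failed to recruit the smallest afferent")
    if not ff_spiked[0]:
        raise ConfigurationError(
            "afferent->FF gap coupling is too weak to recruit the paired "
            "FF cell from a single afferent spike")
    return {"recruited_afferents": n_recruited,
            "ff_recruited": int(ff_spiked.sum())}
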