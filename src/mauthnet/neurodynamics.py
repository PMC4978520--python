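"""Membrane and synaptic dynamics for the Mauthner escape circuit.

Three cell classes are simulated:

* conductance-based leaky integrate-and-fire (LIF) neurons for the Mauthner
  cells and the feedforward (FF) glycinergic interneurons,
* Hodgkin-Huxley (HH) neurons for the VIIIth-ganglion auditory afferents,
  whose membrane surface area gradient implements stimulus-strength-dependent
  recruitment,

coupled by delayed single-exponential chemical synapses (glycine, glutamate)
and ohmic gap junctions (afferent -> M-cell with a dendritic low-pass filter,
afferent -> FF one-to-one).

Internal unit system: mV, ms, nA, uS (micro-siemens) and nF.  Conductances in
circuit tables are given in nS and converted on compilation; HH channel
densities are mS/cm^2 over areas in um^2.

Integration is exponential Euler at a fixed step (default dt = 0.01 ms) for
both the LIF equation and the HH gates/voltage; synaptic delays are rounded
to the nearest integer multiple of dt and the rounding is recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import brentq

from .errors import (
    ConfigurationError,
    SimulationDivergenceError,
    SuprathresholdWarning,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .circuit import CircuitSpec

__all__ = [
    "LIFParams",
    "HHParams",
    "SynapseSpec",
    "GapJunctionSpec",
    "TrialRecording",
    "BatchResult",
    "NetworkEngine",
    "integrate_network",
    "lif_response_closed_form",
    "hh_threshold_current",
    "hh_resting_state",
    "UNRECRUITABLE",
]

NS_TO_US = 1e-3  # nS -> uS
UM2_TO_CM2 = 1e-8  # um^2 -> cm^2

#: Sentinel returned by :func:`hh_threshold_current` when no probe current
#: elicits a spike.
UNRECRUITABLE = math.inf

#: Value (mV) drawn into voltage traces at the sample of a LIF spike so that
#: phase-plot analyses see a rising edge; the integrated state resets to
#: ``reset_potential`` regardless.
SPIKE_DRAW_MV = 0.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFParams:
    """Passive and threshold parameters of a conductance-based LIF cell.

    Rm is the input resistance (MOhm), tau_m the membrane time constant (ms);
    the implied capacitance is ``tau_m / Rm`` (nF).  ECl is the glycine/IPSP
    reversal potential used by glycinergic synapses onto this cell class.
    """

    Rm: float  # MOhm
    Erest: float  # mV
    ECl: float  # mV
    Espike: float  # mV
    tau_m: float  # ms
    t_refractory: float = 2.0  # ms
    reset_potential: float | None = None  # mV; defaults to Erest

    def __post_init__(self):
        if self.Rm <= 0 or self.tau_m <= 0:
            raise ConfigurationError("Rm and tau_m must be positive")
        if not self.Espike > self.Erest:
            raise ConfigurationError("Espike must exceed Erest")
        if not (self.Erest - 20.0 <= self.ECl <= self.Espike):
            raise ConfigurationError("ECl must lie in [Erest - 20, Espike]")
        if self.t_refractory < 0:
            raise ConfigurationError("t_refractory must be non-negative")
        if self.reset_potential is None:
            object.__setattr__(self, "reset_potential", self.Erest)

    @property
    def capacitance(self) -> float:
        """Membrane capacitance in nF."""
        return self.tau_m / self.Rm

    @property
    def g_leak(self) -> float:
        """Leak conductance in uS."""
        return 1.0 / self.Rm


@dataclass(frozen=True)
class HHParams:
    """Hodgkin-Huxley parameters for the VIIIth-ganglion afferents.

    Conductances are densities (mS/cm^2); ``surface_areas`` (um^2, ascending)
    set each afferent's absolute conductances and capacitance, which is what
    makes larger cells require more injected current to spike and therefore
    recruit later.  ``v_rest_target`` is the resting potential the gate
    kinetics are shifted to reproduce (matched to the Mauthner cell's rest).
    """

    El: float = -79.0  # mV
    EK: float = -90.0  # mV
    ENa: float = 50.0  # mV
    gl: float = 0.05  # mS/cm^2
    gNa: float = 100.0  # mS/cm^2
    gK: float = 200.0  # mS/cm^2
    surface_areas: tuple[float, ...] = ()
    v_rest_target: float = -79.0  # mV
    cm: float = 1.0  # uF/cm^2

    def __post_init__(self):
        if min(self.gl, self.gNa, self.gK) < 0:
            raise ConfigurationError("conductance densities must be >= 0")
        if not (self.EK < self.El < self.ENa):
            raise ConfigurationError("require EK < El < ENa")
        areas = tuple(float(a) for a in self.surface_areas)
        if any(a <= 0 for a in areas):
            raise ConfigurationError("surface areas must be positive")
        if list(areas) != sorted(areas):
            raise ConfigurationError("surface areas must be sorted ascending")
        object.__setattr__(self, "surface_areas", areas)

    def kinetics_key(self) -> tuple:
        return (self.El, self.EK, self.ENa, self.gl, self.gNa, self.gK,
                self.v_rest_target)


@dataclass(frozen=True)
class SynapseSpec:
    """One chemical synapse group (single-exponential conductance kernel)."""

    name: str
    pre_pop: tuple[str, str]  # (population, side)
    post_pop: tuple[str, str]
    transmitter: str  # 'glycine' | 'glutamate'
    g_peak: float  # nS, increment per presynaptic spike
    delay: float  # ms
    tau_decay: float  # ms
    E_rev: float  # mV
    pattern: str  # 'all_to_one' | 'one_to_one' | 'all_to_all'
    laterality: str  # 'ipsilateral' | 'contralateral'

    def __post_init__(self):
        if self.g_peak < 0 or self.delay < 0 or self.tau_decay <= 0:
            raise ConfigurationError(
                f"synapse group {self.name}: require g_peak >= 0, delay >= 0, "
                "tau_decay > 0"
            )
        if self.transmitter not in ("glycine", "glutamate"):
            raise ConfigurationError(f"unknown transmitter {self.transmitter!r}")
        if self.pattern not in ("all_to_one", "one_to_one", "all_to_all"):
            raise ConfigurationError(f"unknown pattern {self.pattern!r}")


@dataclass(frozen=True)
class GapJunctionSpec:
    """One electrical coupling group, modeled as a unidirectional ohmic drive.

    The postsynaptic cell receives ``I = g_gap * (V_pre - V_post)`` per
    connection; when ``dendritic_tau`` is set the presynaptic voltage is
    low-pass filtered with that time constant first (used for the afferent ->
    Mauthner coupling, standing in for lateral-dendrite filtering).

    ``lumped=True`` reads ``g_gap`` as the compound conductance of the whole
    all-to-one group (split evenly across connections) rather than a
    per-connection value; this keeps the standing electrical load on the
    postsynaptic cell equal to ``g_gap`` regardless of pool size, matching
    an input resistance calibrated with the couplings in place.
    """

    name: str
    pre_pop: tuple[str, str]
    post_pop: tuple[str, str]
    g_gap: float  # nS (per connection, or per group when lumped)
    pattern: str  # 'all_to_one' | 'one_to_one'
    dendritic_tau: float | None = None  # ms
    lumped: bool = False

    def __post_init__(self):
        if self.g_gap < 0:
            raise ConfigurationError(f"gap group {self.name}: g_gap must be >= 0")
        if self.dendritic_tau is not None and self.dendritic_tau <= 0:
            raise ConfigurationError(
                f"gap group {self.name}: dendritic_tau must be > 0"
            )
        if self.pattern not in ("all_to_one", "one_to_one"):
            raise ConfigurationError(f"unknown gap pattern {self.pattern!r}")


# ---------------------------------------------------------------------------
# HH kinetics (Traub-Miles rate set with a solvable threshold shift)
# ---------------------------------------------------------------------------
#
# The afferents use the Traub-Miles m^3 h / n^4 rate functions parameterized
# by a threshold-shift voltage VT (the convention of the common
# conductance-based network HH variant).  VT is solved numerically so that
# the self-consistent resting potential of the full channel set equals
# v_rest_target: at the leak reversal the small sodium window current always
# exceeds the (nearly closed) potassium current, so rest approaches the leak
# reversal from above as VT grows; we place it 0.005 mV above the target,
# well inside the 0.01 mV equilibrium tolerance used by the tests.


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (exp(x / y) - 1), stable at x -> 0 (limit y)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-9
    safe = np.where(small, 1.0, x)
    out = safe / np.expm1(safe / y)
    return np.where(small, y, out)


def _tm_rates(v, VT: float):
    """Traub-Miles rate functions (1/ms) at membrane potential v (mV)."""
    v = np.asarray(v, dtype=float)
    u = v - VT
    am = 0.32 * _vtrap(13.0 - u, 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    ah = 0.128 * np.exp((17.0 - u) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
    an = 0.032 * _vtrap(15.0 - u, 5.0)
    bn = 0.5 * np.exp((10.0 - u) / 40.0)
    return am, bm, ah, bh, an, bn


def _gate_inf(v, VT: float):
    am, bm, ah, bh, an, bn = _tm_rates(v, VT)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _membrane_current_density(v: float, VT: float, p: HHParams) -> float:
    """Steady-state membrane current density (uA/cm^2, depolarizing > 0)."""
    minf, hinf, ninf = _gate_inf(v, VT)
    return float(
        p.gl * (p.El - v)
        + p.gNa * minf**3 * hinf * (p.ENa - v)
        + p.gK * ninf**4 * (p.EK - v)
    )


def _resting_potential(VT: float, p: HHParams) -> float:
    """Self-consistent resting potential for a given threshold shift."""
    lo = p.EK + 0.5
    hi = lo
    f_lo = _membrane_current_density(lo, VT, p)
    # march upward to bracket the lowest zero crossing
    for hi in np.arange(lo + 1.0, -30.0, 1.0):
        f_hi = _membrane_current_density(hi, VT, p)
        if f_lo > 0 >= f_hi or f_lo >= 0 > f_hi:
            return brentq(_membrane_current_density, hi - 1.0, hi,
                          args=(VT, p), xtol=1e-12)
        f_lo, lo = f_hi, hi
    raise ConfigurationError("no resting fixed point found for HH parameters")


_REST_OFFSET = 0.005  # mV above v_rest_target at which rest is pinned
_equilibrium_cache: dict[tuple, tuple[float, float, float, float, float]] = {}


def hh_resting_state(params: HHParams) -> tuple[float, float, float, float, float]:
    """Solve the afferent kinetics shift and resting state.

    Returns ``(VT, V_rest, m0, h0, n0)`` where VT is the rate-function
    threshold shift that places the self-consistent resting potential within
    0.005 mV of ``v_rest_target``, and the gate values are their steady
    states at that rest.
    """
    key = params.kinetics_key()
    if key not in _equilibrium_cache:
        target = params.v_rest_target + _REST_OFFSET

        def offset(VT):
            return _resting_potential(VT, params) - target

        lo, hi = params.v_rest_target - 25.0, params.v_rest_target + 25.0
        VT = brentq(offset, lo, hi, xtol=1e-10)
        v0 = _resting_potential(VT, params)
        m0, h0, n0 = _gate_inf(v0, VT)
        _equilibrium_cache[key] = (float(VT), float(v0), float(m0), float(h0),
                                   float(n0))
    return _equilibrium_cache[key]


_V_TABLE_MIN = -130.0
_V_TABLE_MAX = 70.0
_V_TABLE_STEP = 0.005
_rate_table_cache: dict[tuple, dict[str, np.ndarray]] = {}


def _rate_tables(params: HHParams, VT: float, dt: float) -> dict[str, np.ndarray]:
    """Tabulated gate steady states and per-step decay factors on a V grid."""
    key = (params.kinetics_key(), round(VT, 9), round(dt, 9))
    if key not in _rate_table_cache:
        v = np.arange(_V_TABLE_MIN, _V_TABLE_MAX + _V_TABLE_STEP / 2,
                      _V_TABLE_STEP)
        am, bm, ah, bh, an, bn = _tm_rates(v, VT)
        tables = {
            "minf": am / (am + bm), "mfac": np.exp(-dt * (am + bm)),
            "hinf": ah / (ah + bh), "hfac": np.exp(-dt * (ah + bh)),
            "ninf": an / (an + bn), "nfac": np.exp(-dt * (an + bn)),
        }
        # fused layout: one gather yields all six gate quantities
        tables["stacked"] = np.stack(
            [tables[k] for k in ("minf", "mfac", "hinf", "hfac",
                                 "ninf", "nfac")], axis=1).copy()
        _rate_table_cache[key] = tables
    return _rate_table_cache[key]


def _v_index(V: np.ndarray) -> np.ndarray:
    idx = (V - _V_TABLE_MIN) * (1.0 / _V_TABLE_STEP)
    return np.clip(idx, 0, int((_V_TABLE_MAX - _V_TABLE_MIN) / _V_TABLE_STEP)
                   ).astype(np.int32)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


@dataclass
class TrialRecording:
    """Traces, spikes and synaptic conductances for one simulated protocol.

    ``voltages`` maps ``(population, side)`` to an array of shape
    ``(n_cells, n_samples)``; ``spikes`` maps the same keys to per-cell
    arrays of spike times (ms, on the time grid, strictly increasing);
    ``conductances`` maps chemical group names to ``(n_post, n_samples)``
    arrays in nS.  LIF spike samples are drawn at ``SPIKE_DRAW_MV`` in the
    voltage traces (the integrated state resets immediately).
    """

    dt: float
    t: np.ndarray
    voltages: dict[tuple[str, str], np.ndarray]
    spikes: dict[tuple[str, str], list[np.ndarray]]
    conductances: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def v(self, pop: str, side: str, cell: int = 0) -> np.ndarray:
        return self.voltages[(pop, side)][cell]

    def spike_times(self, pop: str, side: str, cell: int = 0) -> np.ndarray:
        return self.spikes[(pop, side)][cell]

    def first_spike(self, pop: str, side: str, cell: int = 0) -> float:
        st = self.spike_times(pop, side, cell)
        return float(st[0]) if st.size else math.nan

    def voltage_frame(self):
        """Tidy voltage table (time_ms, population, side, cell_index, v_mV)."""
        import pandas as pd

        rows = []
        for (pop, side), arr in self.voltages.items():
            for i in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "time_ms": self.t, "population": pop, "side": side,
                    "cell_index": i, "v_mV": arr[i],
                }))
        return pd.concat(rows, ignore_index=True)

    def spike_frame(self):
        """Tidy spike table (population, side, cell_index, t_spike_ms)."""
        import pandas as pd

        rows = {"population": [], "side": [], "cell_index": [],
                "t_spike_ms": []}
        for (pop, side), per_cell in self.spikes.items():
            for i, st in enumerate(per_cell):
                rows["population"].extend([pop] * len(st))
                rows["side"].extend([side] * len(st))
                rows["cell_index"].extend([i] * len(st))
                rows["t_spike_ms"].extend(st.tolist())
        return pd.DataFrame(rows)

    def save(self, prefix) -> None:
        """Write voltage/spike CSVs and a JSON metadata sidecar."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.voltage_frame().to_csv(f"{prefix}_voltages.csv", index=False)
        self.spike_frame().to_csv(f"{prefix}_spikes.csv", index=False)
        meta = dict(self.metadata)
        meta["dt_ms"] = self.dt
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


@dataclass
class BatchResult:
    """Spike bookkeeping for a batch of sweep conditions.

    ``first_spike`` holds the first spike time (ms, NaN if none) per
    condition and cell; ``n_spikes`` the spike counts.  Keys are
    ``(population, side)``.
    """

    dt: float
    t_end: float
    first_spike: dict[tuple[str, str], np.ndarray]
    n_spikes: dict[tuple[str, str], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def m_first(self, side: str) -> np.ndarray:
        return self.first_spike[("M", side)][:, 0]


# ---------------------------------------------------------------------------
# compiled network engine
# ---------------------------------------------------------------------------


_LIF_ORDER = (("M", "left"), ("M", "right"), ("FF", "left"), ("FF", "right"))
_HH_ORDER = (("auditory", "left"), ("auditory", "right"))


@dataclass
class _ChemGroup:
    name: str
    pre_kind: str  # 'lif' | 'hh'
    pre_idx: np.ndarray
    post_idx: np.ndarray
    pattern: str
    g_peak_us: float
    delay_steps: int
    delay_rounding: float
    decay: float
    E_rev: float


@dataclass
class _GapGroup:
    name: str
    pre_idx: np.ndarray  # positions into the HH array
    post_idx: np.ndarray  # positions into the LIF array
    pattern: str
    g_us: float
    filter_decay: float | None  # per-step decay of the dendritic low-pass


class NetworkEngine:
    """Compiled fixed-step integrator for one circuit.

    The engine is built once per (circuit, dt) and can run single richly
    recorded trials (:meth:`run`) or large batches of stimulus conditions
    with spike-only recording (:meth:`run_batch`).  All cells start at the
    coupled resting fixed point, so an undriven network is stationary.
    """

    def __init__(self, circuit: "CircuitSpec", dt: float | None = None):
        self.circuit = circuit
        self.dt = float(dt if dt is not None else circuit.dt)
        if self.dt > 0.025:
            raise ConfigurationError("dt must be <= 0.025 ms")
        self._compile()

    # -- compilation -----------------------------------------------------

    def _compile(self) -> None:
        c = self.circuit
        # LIF layout
        self.lif_keys: list[tuple[str, str]] = []
        self.lif_slices: dict[tuple[str, str], slice] = {}
        self.lif_cell_ids: dict[tuple[str, str], np.ndarray] = {}
        C, gL, Erest, Espike, reset, refr = [], [], [], [], [], []
        pos = 0
        for key in _LIF_ORDER:
            pop = c.populations.get(key)
            if pop is None or pop.n == 0:
                continue
            p: LIFParams = pop.params
            self.lif_keys.append(key)
            self.lif_slices[key] = slice(pos, pos + pop.n)
            self.lif_cell_ids[key] = np.asarray(pop.cell_ids, dtype=int)
            C += [p.capacitance] * pop.n
            gL += [p.g_leak] * pop.n
            Erest += [p.Erest] * pop.n
            Espike += [p.Espike] * pop.n
            reset += [p.reset_potential] * pop.n
            refr += [max(1, int(round(p.t_refractory / self.dt)))] * pop.n
            pos += pop.n
        self.n_lif = pos
        self.lif_C = np.array(C)
        self.lif_gL = np.array(gL)
        self.lif_Erest = np.array(Erest)
        self.lif_Espike = np.array(Espike)
        self.lif_reset = np.array(reset)
        self.lif_refr_steps = np.array(refr, dtype=np.int32)

        # HH layout
        self.hh_keys: list[tuple[str, str]] = []
        self.hh_slices: dict[tuple[str, str], slice] = {}
        self.hh_cell_ids: dict[tuple[str, str], np.ndarray] = {}
        areas = []
        pos = 0
        self.hh_params: HHParams | None = None
        for key in _HH_ORDER:
            pop = c.populations.get(key)
            if pop is None or pop.n == 0:
                continue
            self.hh_params = pop.params
            self.hh_keys.append(key)
            self.hh_slices[key] = slice(pos, pos + pop.n)
            self.hh_cell_ids[key] = np.asarray(pop.cell_ids, dtype=int)
            areas += [pop.params.surface_areas[i] for i in pop.cell_ids]
            pos += pop.n
        self.n_hh = pos
        if self.n_hh:
            p = self.hh_params
            area_cm2 = np.array(areas) * UM2_TO_CM2
            self.hh_C = p.cm * area_cm2 * 1e3  # nF
            self.hh_gl = p.gl * area_cm2 * 1e3  # uS
            self.hh_gNa = p.gNa * area_cm2 * 1e3
            self.hh_gK = p.gK * area_cm2 * 1e3
            VT, v0, m0, h0, n0 = hh_resting_state(p)
            self.hh_VT = VT
            self.hh_v0, self.hh_m0, self.hh_h0, self.hh_n0 = v0, m0, h0, n0
            self.hh_tables = _rate_tables(p, VT, self.dt)

        def _positions(key, kind):
            sl = (self.lif_slices if kind == "lif" else self.hh_slices)[key]
            return np.arange(sl.start, sl.stop)

        # chemical groups
        self.chem: list[_ChemGroup] = []
        self.delay_roundings: dict[str, float] = {}
        for syn in c.synapses:
            pre_kind = "hh" if syn.pre_pop[0] == "auditory" else "lif"
            if syn.pre_pop not in (self.lif_slices if pre_kind == "lif"
                                   else self.hh_slices):
                raise ConfigurationError(
                    f"synapse group {syn.name}: unknown pre population "
                    f"{syn.pre_pop}")
            if syn.post_pop not in self.lif_slices:
                raise ConfigurationError(
                    f"synapse group {syn.name}: unknown post population "
                    f"{syn.post_pop}")
            pre_idx = _positions(syn.pre_pop, pre_kind)
            post_idx = _positions(syn.post_pop, "lif")
            if syn.pattern == "one_to_one":
                pre_ids = (self.lif_cell_ids if pre_kind == "lif"
                           else self.hh_cell_ids)[syn.pre_pop]
                post_ids = self.lif_cell_ids[syn.post_pop]
                common = np.intersect1d(pre_ids, post_ids)
                pre_idx = pre_idx[np.isin(pre_ids, common)]
                post_idx = post_idx[np.isin(post_ids, common)]
            steps = int(round(syn.delay / self.dt))
            rounding = steps * self.dt - syn.delay
            self.delay_roundings[syn.name] = rounding
            self.chem.append(_ChemGroup(
                name=syn.name, pre_kind=pre_kind, pre_idx=pre_idx,
                post_idx=post_idx, pattern=syn.pattern,
                g_peak_us=syn.g_peak * NS_TO_US, delay_steps=steps,
                delay_rounding=rounding,
                decay=math.exp(-self.dt / syn.tau_decay), E_rev=syn.E_rev))

        # gap junction groups
        self.gaps: list[_GapGroup] = []
        for gj in c.gap_junctions:
            if gj.pre_pop[0] != "auditory":
                raise ConfigurationError(
                    f"gap group {gj.name}: only afferent-driven gap junctions "
                    "are supported")
            if gj.pre_pop not in self.hh_slices or gj.post_pop not in self.lif_slices:
                raise ConfigurationError(
                    f"gap group {gj.name}: unknown population reference")
            pre_idx = _positions(gj.pre_pop, "hh")
            post_idx = _positions(gj.post_pop, "lif")
            if gj.pattern == "one_to_one":
                pre_ids = self.hh_cell_ids[gj.pre_pop]
                post_ids = self.lif_cell_ids[gj.post_pop]
                common = np.intersect1d(pre_ids, post_ids)
                pre_idx = pre_idx[np.isin(pre_ids, common)]
                post_idx = post_idx[np.isin(post_ids, common)]
            fdec = (math.exp(-self.dt / gj.dendritic_tau)
                    if gj.dendritic_tau else None)
            g_us = gj.g_gap * NS_TO_US
            if gj.lumped and len(pre_idx):
                g_us /= len(pre_idx)
            self.gaps.append(_GapGroup(
                name=gj.name, pre_idx=pre_idx, post_idx=post_idx,
                pattern=gj.pattern, g_us=g_us, filter_decay=fdec))

        # static LIF conductance load (leak + standing gap conductance)
        g_static = self.lif_gL.copy()
        for gj in self.gaps:
            if gj.pattern == "all_to_one":
                g_static[gj.post_idx] += gj.g_us * len(gj.pre_idx)
            else:
                g_static[gj.post_idx] += gj.g_us
        self.lif_g_static = g_static
        self.lif_num_static = self.lif_gL * self.lif_Erest

    # -- cell lookup for diagnostics ------------------------------------

    def _locate_lif(self, pos: int) -> tuple[str, str, int]:
        for key, sl in self.lif_slices.items():
            if sl.start <= pos < sl.stop:
                return key[0], key[1], int(self.lif_cell_ids[key][pos - sl.start])
        raise IndexError(pos)

    def _locate_hh(self, pos: int) -> tuple[str, str, int]:
        for key, sl in self.hh_slices.items():
            if sl.start <= pos < sl.stop:
                return key[0], key[1], int(self.hh_cell_ids[key][pos - sl.start])
        raise IndexError(pos)

    def lif_position(self, pop: str, side: str, cell_id: int) -> int:
        key = (pop, side)
        if key not in self.lif_slices:
            raise ConfigurationError(f"unknown population {key}")
        ids = self.lif_cell_ids[key]
        hits = np.nonzero(ids == cell_id)[0]
        if hits.size == 0:
            raise ConfigurationError(
                f"cell {cell_id} absent from population {key}")
        return self.lif_slices[key].start + int(hits[0])

    # -- main integrator --------------------------------------------------

    def _integrate(
        self,
        B: int,
        n_steps: int,
        *,
        lif_events: dict[int, list[tuple[int, float]]] | None = None,
        hh_current: tuple[np.ndarray, int, int] | None = None,
        forced_spikes: dict[int, list[int]] | None = None,
        record_traces: bool = False,
        record_g: bool = False,
        early_stop_after: int | None = None,
    ):
        """Advance the network ``n_steps`` from rest.

        lif_events: step -> [(lif position, delta current nA)] applied to a
        persistent per-cell injected current (step on/off edges).
        hh_current: (amplitudes (B, n_hh) nA, on_step, off_step).
        forced_spikes: step -> [lif positions] fired irrespective of voltage.
        early_stop_after: earliest step index after which the run may stop
        once the network is quiescent (used by sweeps; traces disable it).
        """
        dt = self.dt
        n_lif, n_hh = self.n_lif, self.n_hh
        V = np.tile(self.lif_Erest, (B, 1))
        I_lif = np.zeros((B, n_lif))
        refr = np.zeros((B, n_lif), dtype=np.int32)
        first_spike = np.full((B, n_lif), np.nan)
        n_spikes = np.zeros((B, n_lif), dtype=np.int32)
        spike_lists: list[list[float]] = [[] for _ in range(n_lif * B)]

        if n_hh:
            Vh = np.full((B, n_hh), self.hh_v0)
            m = np.full((B, n_hh), self.hh_m0)
            h = np.full((B, n_hh), self.hh_h0)
            n_gate = np.full((B, n_hh), self.hh_n0)
            tb = self.hh_tables
            first_spike_hh = np.full((B, n_hh), np.nan)
            n_spikes_hh = np.zeros((B, n_hh), dtype=np.int32)
            hh_spike_lists: list[list[float]] = [[] for _ in range(n_hh * B)]
        # gap-junction dendritic filters start at the presynaptic rest
        gap_filters: list[np.ndarray | None] = []
        for gj in self.gaps:
            gap_filters.append(
                np.full((B, len(gj.pre_idx)), self.hh_v0)
                if gj.filter_decay is not None else None)

        # settle LIF cells at the coupled fixed point (chem conductances are
        # zero at rest; the standing gap load pulls V toward the afferent
        # rest, and currents active from step 0 are included)
        num0 = np.tile(self.lif_num_static, (B, 1))
        if lif_events and 0 in lif_events:
            for pos_i, amp in lif_events[0]:
                I_lif[:, pos_i] += amp
        for gj in self.gaps:
            pre_rest = self.hh_v0
            if gj.pattern == "all_to_one":
                num0[:, gj.post_idx] += gj.g_us * len(gj.pre_idx) * pre_rest
            else:
                num0[:, gj.post_idx] += gj.g_us * pre_rest
        V[:] = (num0 + I_lif) / self.lif_g_static
        hold_flags = V >= self.lif_Espike  # cells driven suprathreshold by DC

        g_chem = [np.zeros((B, len(grp.post_idx))) for grp in self.chem]
        pending: dict[int, list[tuple[int, np.ndarray]]] = {}

        if record_traces:
            V_rec = np.empty((n_steps + 1, B, n_lif))
            V_rec[0] = V
            if n_hh:
                Vh_rec = np.empty((n_steps + 1, B, n_hh))
                Vh_rec[0] = Vh
        if record_g:
            g_rec = [np.zeros((n_steps + 1, B, len(grp.post_idx)))
                     for grp in self.chem]

        hh_amp = hh_on = hh_off = None
        if hh_current is not None:
            hh_amp, hh_on, hh_off = hh_current

        last_spike_step = -1
        check_every = 200
        Espike_row = self.lif_Espike[None, :]
        reset_row = self.lif_reset[None, :]
        inv_C = 1.0 / self.lif_C
        inv_Ch = 1.0 / self.hh_C if n_hh else None

        for t in range(n_steps):
            # scheduled LIF current edges (step 0 already applied pre-settle)
            if lif_events and t in lif_events and t > 0:
                for pos_i, amp in lif_events[t]:
                    I_lif[:, pos_i] += amp

            # ---- HH afferents -----------------------------------------
            if n_hh:
                idx = _v_index(Vh)
                gt = tb["stacked"][idx]
                minf = gt[..., 0]
                m = minf + (m - minf) * gt[..., 1]
                hinf = gt[..., 2]
                h = hinf + (h - hinf) * gt[..., 3]
                ninf = gt[..., 4]
                n_gate = ninf + (n_gate - ninf) * gt[..., 5]
                gna = self.hh_gNa * (m * m * m * h)
                gk = self.hh_gK * (n_gate**4)
                gtot_h = self.hh_gl + gna + gk
                num_h = (self.hh_gl * self.hh_params.El
                         + gna * self.hh_params.ENa + gk * self.hh_params.EK)
                if hh_amp is not None and hh_on <= t < hh_off:
                    num_h = num_h + hh_amp
                veq_h = num_h / gtot_h
                Vh_new = veq_h + (Vh - veq_h) * np.exp(-dt * gtot_h * inv_Ch)
                spk_h = (Vh < 0.0) & (Vh_new >= 0.0)
                Vh = Vh_new

            # dendritic low-pass filters of gap-junction drive
            for gi, gj in enumerate(self.gaps):
                if gap_filters[gi] is not None:
                    pre = Vh[:, gj.pre_idx]
                    gap_filters[gi] = pre + (gap_filters[gi] - pre) * gj.filter_decay

            # ---- chemical conductances --------------------------------
            arrivals = pending.pop(t, None)
            for gi, g in enumerate(g_chem):
                g *= self.chem[gi].decay
            if arrivals:
                for gi, inc in arrivals:
                    g_chem[gi] += inc

            # ---- LIF update -------------------------------------------
            g_tot = np.tile(self.lif_g_static, (B, 1))
            num = np.tile(self.lif_num_static, (B, 1))
            for gi, grp in enumerate(self.chem):
                g = g_chem[gi]
                g_tot[:, grp.post_idx] += g
                num[:, grp.post_idx] += g * grp.E_rev
            for gi, gj in enumerate(self.gaps):
                if gj.pattern == "all_to_one":
                    vf = gap_filters[gi] if gap_filters[gi] is not None \
                        else Vh[:, gj.pre_idx]
                    num[:, gj.post_idx] += gj.g_us * vf.sum(axis=1, keepdims=True)
                else:
                    num[:, gj.post_idx] += gj.g_us * Vh[:, gj.pre_idx]
            num += I_lif
            veq = num / g_tot
            V_new = veq + (V - veq) * np.exp(-dt * g_tot * inv_C)

            in_refr = refr > 0
            if in_refr.any():
                V_new = np.where(in_refr, reset_row, V_new)
                refr = np.where(in_refr, refr - 1, refr)

            spk = (V < Espike_row) & (V_new >= Espike_row) & ~in_refr & ~hold_flags
            if forced_spikes and t in forced_spikes:
                for pos_i in forced_spikes[t]:
                    spk[:, pos_i] = refr[:, pos_i] == 0
            if spk.any():
                V_new = np.where(spk, reset_row, V_new)
                refr = np.where(spk, self.lif_refr_steps[None, :], refr)
                t_spk = (t + 1) * dt
                newly = spk & np.isnan(first_spike)
                first_spike[newly] = t_spk
                n_spikes += spk
                last_spike_step = t
                if record_traces:
                    for b, pos_i in zip(*np.nonzero(spk)):
                        spike_lists[b * n_lif + pos_i].append(t_spk)
                # propagate to delayed chemical arrivals
                for gi, grp in enumerate(self.chem):
                    if grp.pre_kind != "lif":
                        continue
                    inc = self._spike_increment(grp, spk)
                    if inc is not None:
                        pending.setdefault(t + grp.delay_steps, []).append(
                            (gi, inc))
            V = V_new

            if n_hh and spk_h.any():
                t_spk = (t + 1) * dt
                newly = spk_h & np.isnan(first_spike_hh)
                first_spike_hh[newly] = t_spk
                n_spikes_hh += spk_h
                last_spike_step = t
                if record_traces:
                    for b, pos_i in zip(*np.nonzero(spk_h)):
                        hh_spike_lists[b * n_hh + pos_i].append(t_spk)
                for gi, grp in enumerate(self.chem):
                    if grp.pre_kind != "hh":
                        continue
                    inc = self._spike_increment(grp, spk_h)
                    if inc is not None:
                        pending.setdefault(t + grp.delay_steps, []).append(
                            (gi, inc))

            # ---- recording & housekeeping -----------------------------
            if record_traces:
                drawn = np.where(spk, SPIKE_DRAW_MV, V)
                V_rec[t + 1] = drawn
                if n_hh:
                    Vh_rec[t + 1] = Vh
            if record_g:
                for gi, g in enumerate(g_chem):
                    g_rec[gi][t + 1] = g

            if (t + 1) % check_every == 0:
                if not np.isfinite(V).all():
                    b, pos_i = np.argwhere(~np.isfinite(V))[0]
                    pop, side, cid = self._locate_lif(int(pos_i))
                    raise SimulationDivergenceError(pop, side, cid, (t + 1) * dt)
                if n_hh and not np.isfinite(Vh).all():
                    b, pos_i = np.argwhere(~np.isfinite(Vh))[0]
                    pop, side, cid = self._locate_hh(int(pos_i))
                    raise SimulationDivergenceError(pop, side, cid, (t + 1) * dt)
                if (early_stop_after is not None and t >= early_stop_after
                        and t - last_spike_step > int(5.0 / dt)
                        and not pending
                        and (V < Espike_row - 0.2).all()
                        and all(g.max() < 1e-4 if g.size else True
                                for g in g_chem)):
                    n_steps = t + 1
                    break

        result = {
            "n_steps_run": n_steps,
            "V": V,
            "first_spike": first_spike,
            "n_spikes": n_spikes,
            "hold_flags": hold_flags,
        }
        if n_hh:
            result["first_spike_hh"] = first_spike_hh
            result["n_spikes_hh"] = n_spikes_hh
        if record_traces:
            result["V_rec"] = V_rec[: n_steps + 1]
            result["spike_lists"] = spike_lists
            if n_hh:
                result["Vh_rec"] = Vh_rec[: n_steps + 1]
                result["hh_spike_lists"] = hh_spike_lists
        if record_g:
            result["g_rec"] = [g[: n_steps + 1] for g in g_rec]
        return result

    @staticmethod
    def _spike_increment(grp: _ChemGroup, spk: np.ndarray) -> np.ndarray | None:
        """Conductance increment (B, n_post) delivered by this step's spikes."""
        if grp.pattern in ("all_to_one", "all_to_all"):
            cnt = spk[:, grp.pre_idx].sum(axis=1)
            if not cnt.any():
                return None
            return grp.g_peak_us * cnt[:, None] * np.ones((1, len(grp.post_idx)))
        # one_to_one
        pre_spk = spk[:, grp.pre_idx]
        if not pre_spk.any():
            return None
        return grp.g_peak_us * pre_spk.astype(float)

    # -- public run paths -------------------------------------------------

    def run(
        self,
        protocol=None,
        *,
        t_end: float = 50.0,
        record_g: bool = False,
    ) -> TrialRecording:
        """Simulate one protocol with full voltage/spike recording.

        ``protocol`` is duck-typed: it may provide ``injections`` (tuples of
        ``(population, side, cell_id, amplitude_nA, t_on, t_off)``),
        ``forced_spikes`` (``(population, side, cell_id, t_ms)``),
        ``aud_currents`` (``{side: amplitude_nA}`` applied to every afferent
        on that side) and ``aud_window`` (``(t_on, t_off)``).  ``None`` runs
        the circuit at rest.
        """
        dt = self.dt
        n_steps = int(round(t_end / dt))
        lif_events: dict[int, list[tuple[int, float]]] = {}
        forced: dict[int, list[int]] = {}
        hh_current = None
        meta: dict = {"t_end_ms": t_end, "delay_roundings_ms":
                      dict(self.delay_roundings)}

        if protocol is not None:
            for (pop, side, cid, amp, t_on, t_off) in getattr(
                    protocol, "injections", ()) or ():
                pos = self.lif_position(pop, side, cid)
                on = max(0, int(round(t_on / dt)))
                off = int(round(t_off / dt))
                lif_events.setdefault(on, []).append((pos, amp))
                if off < n_steps:
                    lif_events.setdefault(off, []).append((pos, -amp))
            for (pop, side, cid, t_sp) in getattr(
                    protocol, "forced_spikes", ()) or ():
                pos = self.lif_position(pop, side, cid)
                forced.setdefault(int(round(t_sp / dt)), []).append(pos)
            aud = getattr(protocol, "aud_currents", None)
            if aud:
                amp = np.zeros((1, self.n_hh))
                for side, a in aud.items():
                    key = ("auditory", side)
                    if key not in self.hh_slices:
                        raise ConfigurationError(f"unknown population {key}")
                    amp[:, self.hh_slices[key]] = a
                t_on, t_off = getattr(protocol, "aud_window", (0.0, t_end))
                hh_current = (amp, int(round(t_on / dt)), int(round(t_off / dt)))
            meta["protocol"] = getattr(protocol, "describe", lambda: repr(protocol))()

        res = self._integrate(
            1, n_steps, lif_events=lif_events, hh_current=hh_current,
            forced_spikes=forced, record_traces=True, record_g=record_g)

        n_run = res["n_steps_run"]
        t = np.arange(n_run + 1) * dt
        voltages: dict[tuple[str, str], np.ndarray] = {}
        spikes: dict[tuple[str, str], list[np.ndarray]] = {}
        for key in self.lif_keys:
            sl = self.lif_slices[key]
            voltages[key] = res["V_rec"][:, 0, sl].T.copy()
            spikes[key] = [
                np.asarray(res["spike_lists"][pos], dtype=float)
                for pos in range(sl.start, sl.stop)]
        for key in self.hh_keys:
            sl = self.hh_slices[key]
            voltages[key] = res["Vh_rec"][:, 0, sl].T.copy()
            spikes[key] = [
                np.asarray(res["hh_spike_lists"][pos], dtype=float)
                for pos in range(sl.start, sl.stop)]
        conductances: dict[str, np.ndarray] = {}
        if record_g:
            for gi, grp in enumerate(self.chem):
                conductances[grp.name] = (
                    res["g_rec"][gi][:, 0, :].T / NS_TO_US).copy()
        meta["suprathreshold_hold"] = bool(res["hold_flags"].any())
        return TrialRecording(dt=dt, t=t, voltages=voltages, spikes=spikes,
                              conductances=conductances, metadata=meta)

    def run_batch(
        self,
        amp_left: np.ndarray,
        amp_right: np.ndarray,
        *,
        t_on: float,
        t_off: float,
        t_end: float = 50.0,
        early_stop: bool = True,
    ) -> BatchResult:
        """Simulate a batch of afferent-drive conditions (spike recording only).

        ``amp_left``/``amp_right`` give the absolute current (nA) injected
        into every afferent on that side, one entry per condition.
        """
        amp_left = np.asarray(amp_left, dtype=float)
        amp_right = np.asarray(amp_right, dtype=float)
        if amp_left.shape != amp_right.shape or amp_left.ndim != 1:
            raise ConfigurationError("amplitude vectors must be 1-D and equal length")
        B = amp_left.size
        dt = self.dt
        n_steps = int(round(t_end / dt))
        amp = np.zeros((B, self.n_hh))
        for side, a in (("left", amp_left), ("right", amp_right)):
            key = ("auditory", side)
            if key in self.hh_slices:
                amp[:, self.hh_slices[key]] = a[:, None]
        hh_current = (amp, int(round(t_on / dt)), int(round(t_off / dt)))
        stop_after = (int(round((t_off + 5.0) / dt)) if early_stop else None)
        res = self._integrate(B, n_steps, hh_current=hh_current,
                              early_stop_after=stop_after)
        first: dict[tuple[str, str], np.ndarray] = {}
        counts: dict[tuple[str, str], np.ndarray] = {}
        for key in self.lif_keys:
            sl = self.lif_slices[key]
            first[key] = res["first_spike"][:, sl].copy()
            counts[key] = res["n_spikes"][:, sl].copy()
        for key in self.hh_keys:
            sl = self.hh_slices[key]
            first[key] = res["first_spike_hh"][:, sl].copy()
            counts[key] = res["n_spikes_hh"][:, sl].copy()
        return BatchResult(
            dt=dt, t_end=res["n_steps_run"] * dt, first_spike=first,
            n_spikes=counts,
            metadata={"t_on": t_on, "t_off": t_off,
                      "early_stopped": res["n_steps_run"] < n_steps})


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------


def integrate_network(circuit: "CircuitSpec", protocol=None,
                      dt: float | None = None,
                      t_end: float = 50.0, *,
                      record_g: bool = False) -> TrialRecording:
    """Build an engine for ``circuit`` and simulate one protocol.

    Thin convenience wrapper over :class:`NetworkEngine`; see
    :meth:`NetworkEngine.run` for the protocol contract.
    """
    return NetworkEngine(circuit, dt=dt).run(protocol, t_end=t_end,
                                             record_g=record_g)


def lif_response_closed_form(params: LIFParams, I_step: float,
                             t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form subthreshold LIF step response (no synaptic input).

    ``Erest + Rm * I * (1 - exp(-t / tau_m))``; warns (without clamping) if
    the result reaches spike threshold, where the closed form stops being
    the trajectory of the spiking model.
    """
    t_arr = np.asarray(t, dtype=float)
    v = params.Erest + params.Rm * I_step * (1.0 - np.exp(-t_arr / params.tau_m))
    if np.any(v >= params.Espike):
        warnings.warn(
            "closed-form LIF response crosses spike threshold; the spiking "
            "model would have fired", SuprathresholdWarning, stacklevel=2)
    if np.ndim(t) == 0:
        return float(v)
    return v


def _hh_single_spikes(params: HHParams, areas: np.ndarray,
                      currents: np.ndarray, t_window: float,
                      dt: float) -> np.ndarray:
    """Vectorized single-cell HH runs; True where a 0 mV upstroke occurs."""
    VT, v0, m0, h0, n0 = hh_resting_state(params)
    tb = _rate_tables(params, VT, dt)
    area_cm2 = np.asarray(areas, dtype=float) * UM2_TO_CM2
    C = params.cm * area_cm2 * 1e3
    gl = params.gl * area_cm2 * 1e3
    gNa = params.gNa * area_cm2 * 1e3
    gK = params.gK * area_cm2 * 1e3
    k = area_cm2.size
    V = np.full(k, v0)
    m = np.full(k, m0)
    h = np.full(k, h0)
    n = np.full(k, n0)
    I = np.asarray(currents, dtype=float)
    spiked = np.zeros(k, dtype=bool)
    n_steps = int(round(t_window / dt))
    for _ in range(n_steps):
        idx = _v_index(V)
        minf = tb["minf"][idx]
        m = minf + (m - minf) * tb["mfac"][idx]
        hinf = tb["hinf"][idx]
        h = hinf + (h - hinf) * tb["hfac"][idx]
        ninf = tb["ninf"][idx]
        n = ninf + (n - ninf) * tb["nfac"][idx]
        gna = gNa * (m * m * m * h)
        gk = gK * n**4
        gtot = gl + gna + gk
        veq = (gl * params.El + gna * params.ENa + gk * params.EK + I) / gtot
        V_new = veq + (V - veq) * np.exp(-dt * gtot / C)
        spiked |= (V < 0.0) & (V_new >= 0.0)
        V = V_new
    return spiked


def hh_threshold_current(params: HHParams, area: float | np.ndarray, *,
                         t_window: float = 20.0, dt: float = 0.01,
                         tol_rel: float = 1e-3,
                         i_max: float | None = None) -> float | np.ndarray:
    """Minimal constant current (nA) that makes an afferent of ``area`` spike.

    Bisection between a non-spiking and a spiking probe current, to relative
    tolerance ``tol_rel`` (default 0.1%), with the spike criterion 'at least
    one upward 0 mV crossing within ``t_window`` ms'.  Returns
    :data:`UNRECRUITABLE` (inf) for cells no probe current can recruit.
    Vectorized over ``area``; threshold scales with total conductance and is
    therefore monotone non-decreasing in area.
    """
    areas = np.atleast_1d(np.asarray(area, dtype=float))
    if i_max is None:
        # generous cap: current that would statically depolarize by 300 mV
        i_max = float(np.max(params.gl * areas * UM2_TO_CM2 * 1e3) * 300.0 * 50)
    lo = np.zeros_like(areas)
    hi = np.full_like(areas, np.nan)
    probe = np.full_like(areas, 1e-4)
    unresolved = np.ones_like(areas, dtype=bool)
    while unresolved.any() and probe[unresolved].min() <= i_max:
        spk = _hh_single_spikes(params, areas, probe, t_window, dt)
        newly = spk & unresolved
        hi[newly] = probe[newly]
        unresolved &= ~spk
        lo[unresolved & (probe > lo)] = probe[unresolved & (probe > lo)]
        probe = probe * 2.0
    out = np.full_like(areas, UNRECRUITABLE)
    ok = ~np.isnan(hi)
    if ok.any():
        lo_b, hi_b = lo[ok].copy(), hi[ok].copy()
        a_ok = areas[ok]
        while np.max((hi_b - lo_b) / hi_b) > tol_rel:
            mid = 0.5 * (lo_b + hi_b)
            spk = _hh_single_spikes(params, a_ok, mid, t_window, dt)
            hi_b = np.where(spk, mid, hi_b)
            lo_b = np.where(spk, lo_b, mid)
        out[ok] = hi_b
    if np.ndim(area) == 0:
        return float(out[0])
    return out
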