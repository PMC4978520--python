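"""Electrophysiology-style trace analyses, applied to simulated recordings.

These are the calibration procedures of the experimental methods, run on
the model's own traces so the loop closes: input resistance from the
current needed for a -10 mV steady deflection, membrane time constant from
a double-exponential fit of the post-step relaxation (slowest constant
kept), spike threshold from the phase plot (dV/dt vs V), and the chloride
reversal from the linear fit of IPSP peak amplitude against holding
potential.  Estimators are pure functions of traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .circuit import CircuitSpec, build_circuit
from .errors import ExtrapolationWarning, FitError
from .protocols import (
    IpspExperiment,
    StepFamily,
    measure_ipsp,
    passive_steps,
    peak_conductance_ratio,
)

__all__ = [
    "PassiveFitResult",
    "estimate_rm",
    "estimate_tau",
    "estimate_threshold_phaseplot",
    "estimate_ecl",
    "ipsp_amplitudes",
    "run_calibration",
]


@dataclass
class PassiveFitResult:
    """Estimates recovered from simulated traces, with fit diagnostics."""

    rm_hat: float | None = None  # MOhm
    tau_hat: float | None = None  # ms (slowest fitted constant)
    threshold_hat: float | None = None  # mV
    ecl_hat: float | None = None  # mV
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# input resistance
# ---------------------------------------------------------------------------


def estimate_rm(family: StepFamily, *, target_deflection: float = -10.0,
                diagnostics: dict | None = None) -> float:
    """Input resistance (MOhm) from a hyperpolarizing current-step family.

    Interpolates between probe currents for the current producing the
    target steady deflection (default -10 mV below rest) and returns
    ``|target| / |I|``.
    """
    currents = np.asarray(family.currents, dtype=float)
    defl = np.array([family.deflection(i) for i in range(len(currents))])
    order = np.argsort(currents)
    currents, defl = currents[order], defl[order]
    if not (np.all(np.diff(defl) > 0) or np.all(np.diff(defl) < 0)):
        raise FitError("voltage deflection is not monotone in current")
    if not (defl.min() <= target_deflection <= defl.max()):
        raise FitError(
            f"steps do not bracket the {target_deflection} mV deflection "
            f"(range {defl.min():.2f} .. {defl.max():.2f} mV)")
    i_target = float(np.interp(target_deflection, defl, currents))
    if i_target == 0:
        raise FitError("zero current maps to the target deflection")
    rm = abs(target_deflection) / abs(i_target)
    if diagnostics is not None:
        diagnostics.update(currents_nA=currents.tolist(),
                           deflections_mV=defl.tolist(),
                           i_target_nA=i_target)
    return rm


# ---------------------------------------------------------------------------
# membrane time constant
# ---------------------------------------------------------------------------


def _double_exp(t, v_inf, a1, tau1, a2, tau2):
    return v_inf + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def estimate_tau(t: np.ndarray, v: np.ndarray, *,
                 diagnostics: dict | None = None) -> float:
    """Slowest time constant (ms) of a double-exponential relaxation fit.

    Constrained nonlinear least squares with multi-start over log-spaced
    initial time-constant pairs; for effectively single-exponential input
    the slow component (the one with non-negligible amplitude) is returned.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size < 10:
        raise FitError("relaxation segment too short to fit")
    span = float(v[0] - v[-1])
    v_inf0 = float(v[-1])
    if abs(span) < 1e-9:
        raise FitError("flat relaxation segment; nothing to fit")
    t_total = t[-1] - t[0]
    best = None
    scales = np.geomspace(t_total / 200.0, t_total / 2.0, 6)
    for tau1_0 in scales:
        for ratio in (3.0, 10.0):
            tau2_0 = tau1_0 / ratio
            p0 = [v_inf0, 0.7 * span, tau1_0, 0.3 * span, tau2_0]
            try:
                popt, _ = curve_fit(
                    _double_exp, t, v, p0=p0,
                    bounds=([-np.inf, -np.inf, 1e-6, -np.inf, 1e-6],
                            [np.inf, np.inf, 100 * t_total, np.inf,
                             100 * t_total]),
                    maxfev=20000, xtol=1e-12, ftol=1e-12)
            except RuntimeError:
                continue
            resid = float(np.sum((_double_exp(t, *popt) - v) ** 2))
            if best is None or resid < best[0]:
                best = (resid, popt)
    if best is None:
        raise FitError("double-exponential fit failed to converge from all starts")
    resid, (v_inf, a1, tau1, a2, tau2) = best
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - resid / ss_tot if ss_tot > 0 else np.nan
    # ignore a vanishing-amplitude component (degenerate single-exponential)
    amp_floor = 1e-3 * abs(span)
    taus = [(tau, a) for tau, a in ((tau1, a1), (tau2, a2))
            if abs(a) > amp_floor]
    if not taus:
        raise FitError("both fitted amplitudes are negligible")
    tau_slow = max(tau for tau, _ in taus)
    if diagnostics is not None:
        diagnostics.update(residual_ss=resid, r_squared=r2, v_inf=v_inf,
                           components=[(float(a1), float(tau1)),
                                       (float(a2), float(tau2))])
    return float(tau_slow)


# ---------------------------------------------------------------------------
# spike threshold from phase plot
# ---------------------------------------------------------------------------


def estimate_threshold_phaseplot(t: np.ndarray, v: np.ndarray, *,
                                 criterion: float = 10.0) -> float:
    """Spike threshold (mV): V where dV/dt first exceeds the criterion.

    ``criterion`` is in mV/ms, applied on the rising limb of the first
    spike.  Works for both HH upstrokes and LIF traces (whose spike sample
    is drawn as a rising edge).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    dvdt = np.diff(v) / np.diff(t)
    rising = np.nonzero(dvdt >= criterion)[0]
    if rising.size == 0:
        raise FitError(
            f"dV/dt never exceeds the {criterion} mV/ms criterion")
    return float(v[rising[0]])


# ---------------------------------------------------------------------------
# chloride reversal from IPSP amplitudes
# ---------------------------------------------------------------------------


def ipsp_amplitudes(exp: IpspExperiment, *, window: float = 15.0,
                    baseline: float = 1.0,
                    cell: str = "ipsi") -> tuple[np.ndarray, np.ndarray]:
    """(holding potentials, signed peak IPSP amplitudes) for one M-cell.

    The amplitude is the extremal deviation from the pre-arrival baseline
    (mean over ``baseline`` ms before synaptic arrival) within ``window``
    ms after arrival.  Flagged (suprathreshold-holding) trials are skipped.
    """
    key = exp.ipsi_key if cell == "ipsi" else exp.contra_key
    holds, amps = [], []
    for amp_nA, rec in exp.recordings.items():
        if amp_nA in exp.flagged:
            continue
        pop, side = key
        v = rec.v(pop, side, 0)
        t = rec.t
        pre = (t >= exp.arrival_time - baseline) & (t < exp.arrival_time)
        post = (t >= exp.arrival_time) & (t <= exp.arrival_time + window)
        v0 = float(v[pre].mean())
        dev = v[post] - v0
        peak = dev[np.argmax(np.abs(dev))]
        holds.append(v0)
        amps.append(float(peak))
    return np.asarray(holds), np.asarray(amps)


def estimate_ecl(exp: IpspExperiment, *, window: float = 15.0,
                 baseline: float = 1.0, cell: str = "ipsi",
                 diagnostics: dict | None = None) -> float:
    """Chloride reversal (mV): zero-amplitude intercept of the linear fit
    of IPSP peak amplitude against holding potential."""
    holds, amps = ipsp_amplitudes(exp, window=window, baseline=baseline,
                                  cell=cell)
    if holds.size < 3:
        raise FitError("need at least 3 usable holding levels")
    if np.max(np.abs(amps)) < 1e-9:
        raise FitError("all IPSP amplitudes are zero (no synaptic input?)")
    if np.all(amps > 0) or np.all(amps < 0):
        warnings.warn(
            "holding potentials all lie on one side of the reversal; the "
            "intercept is an extrapolation", ExtrapolationWarning,
            stacklevel=2)
    slope, intercept = np.polyfit(holds, amps, 1)
    if slope == 0:
        raise FitError("degenerate fit: amplitude does not depend on holding")
    pred = slope * holds + intercept
    ss_res = float(np.sum((amps - pred) ** 2))
    ss_tot = float(np.sum((amps - amps.mean()) ** 2))
    if diagnostics is not None:
        diagnostics.update(slope=float(slope), intercept=float(intercept),
                           r_squared=1.0 - ss_res / ss_tot if ss_tot else np.nan,
                           holding_mV=holds.tolist(),
                           amplitude_mV=amps.tolist())
    return float(-intercept / slope)


# ---------------------------------------------------------------------------
# full calibration loop
# ---------------------------------------------------------------------------


def run_calibration(circuit: CircuitSpec | None = None) -> dict:
    """Build the default circuit, simulate the four calibration protocols,
    and check the recovered parameters against their configured values.

    Returns a report keyed by parameter name, each entry holding the
    configured value, the estimate, the relative/absolute error and a
    pass flag at the stated tolerance (2% for Rm and tau, 0.5 mV for ECl,
    1% for the contra/ipsi conductance ratio, 0.5 mV for threshold).
    """
    circuit = circuit if circuit is not None else build_circuit()
    cfg = circuit.config
    report: dict[str, dict] = {}

    def entry(name, expected, got, tol, mode):
        err = abs(got - expected) / abs(expected) if mode == "rel" else abs(
            got - expected)
        report[name] = {
            "expected": expected, "estimate": got,
            ("rel_error" if mode == "rel" else "abs_error_mV"): err,
            "tolerance": tol, "passed": bool(err <= tol)}

    for pop in ("M", "FF"):
        rm_true = cfg["lif"][pop]["Rm"]
        tau_true = cfg["lif"][pop]["tau_m"]
        base = -10.0 / rm_true  # current for a -10 mV deflection
        fam = passive_steps(circuit, pop, "left",
                            [0.5 * base, 0.9 * base, 1.1 * base, 1.5 * base])
        diag: dict = {}
        rm_hat = estimate_rm(fam, diagnostics=diag)
        entry(f"Rm_{pop}_MOhm", rm_true, rm_hat, 0.02, "rel")
        t_rel, v_rel = fam.relaxation(np.argmin(np.abs(
            fam.currents - 1.5 * base)))
        tau_hat = estimate_tau(t_rel, v_rel)
        entry(f"tau_{pop}_ms", tau_true, tau_hat, 0.02, "rel")

    # spike threshold from a suprathreshold step on the isolated M-cell
    espike = cfg["lif"]["M"]["Espike"]
    rm_true = cfg["lif"]["M"]["Rm"]
    fam = passive_steps(circuit, "M", "left",
                        [2.5 * (espike - cfg["lif"]["M"]["Erest"]) / rm_true],
                        duration=30.0, post=10.0)
    thr_hat = estimate_threshold_phaseplot(fam.t, fam.traces[0])
    entry("Espike_M_mV", espike, thr_hat, 0.5, "abs")

    # IPSP series: reversal and contra/ipsi conductance ratio
    exp = measure_ipsp(circuit, [-1.5, -1.0, -0.5, 0.0, 0.5, 1.0])
    ecl_hat = estimate_ecl(exp)
    entry("ECl_M_mV", cfg["lif"]["M"]["ECl"], ecl_hat, 0.5, "abs")
    ratio_hat = peak_conductance_ratio(exp)
    entry("contra_ipsi_ratio", cfg["synapses"]["ff_contra_m_ratio"],
          ratio_hat, 0.01, "rel")

    report["all_passed"] = all(
        v["passed"] for k, v in report.items() if isinstance(v, dict))
    return report
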