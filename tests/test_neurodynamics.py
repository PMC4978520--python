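"""Membrane/synapse dynamics: equilibria, closed forms, oracles, invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mauthnet import build_circuit
from mauthnet.errors import ConfigurationError, SuprathresholdWarning
from mauthnet.neurodynamics import (
    HHParams,
    LIFParams,
    NetworkEngine,
    UNRECRUITABLE,
    hh_resting_state,
    hh_threshold_current,
    lif_response_closed_form,
)
from mauthnet.protocols import (
    ProtocolSpec,
    drive_protocol,
    measure_ipsp,
    passive_steps,
)

M_PARAMS = LIFParams(Rm=10.0, Erest=-79.0, ECl=-75.0, Espike=-61.0, tau_m=23.0)


class TestLIFClosedForm:
    @pytest.mark.parametrize(
        "current, t, expected",
        [
            (-1.0, 1e9, -89.0),  # steady state: Erest + Rm*I
            (-1.0, 23.0, -79.0 - 10.0 * (1.0 - np.exp(-1.0))),  # one tau
            (0.0, 17.0, -79.0),  # zero input stays at rest
        ],
    )
    def test_step_response(self, current, t, expected):
        assert lif_response_closed_form(M_PARAMS, current, t) == pytest.approx(
            expected, abs=1e-9)

    def test_suprathreshold_is_flagged_not_clamped(self):
        with pytest.warns(SuprathresholdWarning):
            v = lif_response_closed_form(M_PARAMS, 5.0, 1e9)
        assert v == pytest.approx(-29.0)  # not clamped at Espike


class TestParamValidation:
    def test_lif_invariants(self):
        with pytest.raises(ConfigurationError):
            LIFParams(Rm=-1, Erest=-79, ECl=-75, Espike=-61, tau_m=23)
        with pytest.raises(ConfigurationError):
            LIFParams(Rm=10, Erest=-61, ECl=-75, Espike=-79, tau_m=23)
        p = LIFParams(Rm=10, Erest=-79, ECl=-75, Espike=-61, tau_m=23)
        assert p.capacitance == pytest.approx(2.3)
        assert p.reset_potential == -79.0

    def test_hh_invariants(self):
        with pytest.raises(ConfigurationError):
            HHParams(EK=-50, El=-79, ENa=50)
        with pytest.raises(ConfigurationError):
            HHParams(surface_areas=(3.0, 2.0))


class TestEquilibrium:
    def test_isolated_populations_hold_rest_for_one_second(self):
        # all couplings zeroed: every cell must sit at its configured rest
        circ = build_circuit().isolated()
        rec = NetworkEngine(circ, dt=0.025).run(None, t_end=1000.0)
        for (pop, side), target in ((("M", "left"), -79.0),
                                    (("FF", "right"), -77.0),
                                    (("auditory", "left"), -79.0)):
            v = rec.voltages[(pop, side)]
            assert np.abs(v - target).max() < 0.01, (pop, side)
            assert all(len(s) == 0 for s in rec.spikes[(pop, side)])

    def test_coupled_circuit_is_stationary(self, default_circuit):
        rec = NetworkEngine(default_circuit).run(None, t_end=100.0)
        for key, v in rec.voltages.items():
            drift = np.abs(v[:, -1] - v[:, 0]).max()
            assert drift < 1e-6, key
            assert all(len(s) == 0 for s in rec.spikes[key])

    def test_hh_resting_state_matches_target(self):
        p = HHParams(surface_areas=(2000.0,))
        _, v0, m0, h0, n0 = hh_resting_state(p)
        assert v0 == pytest.approx(-79.0, abs=0.01)
        assert 0 < m0 < 0.05 and 0.9 < h0 < 1 and 0 < n0 < 0.05


class TestStepResponses:
    def test_mauthner_input_resistance_deflection(self, default_circuit):
        # -1 nA into a 10 MOhm cell deflects by -10 mV at steady state
        fam = passive_steps(default_circuit, "M", "left", [-1.0])
        assert fam.deflection(0) == pytest.approx(-10.0, rel=1e-3)

    def test_exponential_euler_is_exact_for_the_passive_cell(self,
                                                            default_circuit):
        fam = passive_steps(default_circuit, "M", "left", [-0.5],
                            duration=60.0, post=5.0)
        sel = (fam.t >= fam.onset) & (fam.t <= fam.offset)
        t_rel = fam.t[sel] - fam.onset
        expected = lif_response_closed_form(M_PARAMS, -0.5, t_rel)
        assert np.abs(fam.traces[0][sel] - expected).max() < 1e-9


class TestSynapticDynamics:
    def test_single_ff_ipsp_matches_adaptive_reference(self, default_circuit):
        """Engine IPSP peak vs an adaptive-step reference integration."""
        exp = measure_ipsp(default_circuit, [0.0])
        rec = exp.recordings[0.0]
        v = rec.v("M", "left")
        t = rec.t
        p = M_PARAMS
        g0 = 25e-3  # uS
        t0 = exp.arrival_time

        def rhs(tt, y):
            g = g0 * np.exp(-(tt - t0) / 2.0) if tt >= t0 else 0.0
            return ((p.Erest - y[0]) / p.Rm + g * (p.ECl - y[0])) / p.capacitance

        ref = solve_ivp(rhs, (0.0, 30.0), [p.Erest], max_step=0.05,
                        rtol=1e-10, atol=1e-12, dense_output=True)
        vv = ref.sol(t)[0]
        peak_ref = np.max(vv - p.Erest)
        peak_sim = np.max(v - v[0])
        assert peak_sim == pytest.approx(peak_ref, rel=0.01)
        assert peak_ref > 0.05  # depolarizing from rest (ECl above Erest)

    def test_reversal_null_deflection_at_ecl(self, default_circuit):
        # hold the M-cell exactly at ECl: a glycinergic input must not move it
        hold = (M_PARAMS.ECl - M_PARAMS.Erest) / M_PARAMS.Rm  # 0.4 nA
        exp = measure_ipsp(default_circuit, [hold])
        rec = exp.recordings[hold]
        v = rec.v("M", "left")
        sel = rec.t >= exp.arrival_time
        assert np.abs(v[sel] - M_PARAMS.ECl).max() < 0.05

    def test_delay_fidelity(self, default_circuit):
        """Conductance onset lags the presynaptic spike by the set delay."""
        exp = measure_ipsp(default_circuit, [0.0])
        rec = exp.recordings[0.0]
        g = rec.conductances["FF.left->M.left:glycine"][0]
        t_on = rec.t[np.nonzero(g > 0)[0][0]]
        ff_spike = rec.first_spike("FF", "left", 0)
        assert t_on - ff_spike == pytest.approx(0.3, abs=rec.dt + 1e-9)

    def test_refractoriness(self, default_circuit):
        proto = ProtocolSpec(kind="current_step",
                             injections=(("M", "left", 0, 8.0, 5.0, 60.0),))
        rec = NetworkEngine(default_circuit.isolated()).run(proto, t_end=60.0)
        st = rec.spike_times("M", "left")
        assert len(st) >= 3
        assert np.diff(st).min() >= 2.0 - 1e-9


class TestConvergence:
    def test_halving_dt_preserves_spikes_and_peaks(self, default_circuit):
        """At the default step, halving dt moves no spike by more than dt."""
        recs = {}
        for dt in (0.01, 0.005):
            eng = NetworkEngine(default_circuit, dt=dt)
            recs[dt] = eng.run(drive_protocol(default_circuit, 20.0, 0.0),
                               t_end=30.0)
        for key in (("M", "left"), ("FF", "left"), ("auditory", "left")):
            coarse = np.array([s[0] if len(s) else np.nan
                               for s in recs[0.01].spikes[key]])
            fine = np.array([s[0] if len(s) else np.nan
                             for s in recs[0.005].spikes[key]])
            assert np.array_equal(np.isnan(coarse), np.isnan(fine)), key
            both = ~np.isnan(coarse)
            assert np.nanmax(np.abs(coarse[both] - fine[both])) <= 0.01 + 1e-9
        v_coarse = recs[0.01].v("M", "right").max()
        v_fine = recs[0.005].v("M", "right").max()
        assert v_coarse == pytest.approx(v_fine, rel=5e-3)


class TestHHThreshold:
    def test_monotone_in_area_and_density_scaling(self):
        areas = np.array([2000.0, 4000.0, 20000.0])
        p = HHParams(surface_areas=tuple(areas))
        th = hh_threshold_current(p, areas, t_window=20.0)
        assert np.all(np.diff(th) > 0)
        # density model: doubling the area doubles the threshold current
        assert th[1] == pytest.approx(2 * th[0], rel=5e-3)
        assert th[2] >= th[0]

    def test_bisection_agrees_with_brute_force_sweep(self):
        from mauthnet.neurodynamics import _hh_single_spikes

        p = HHParams(surface_areas=(5000.0,))
        th = hh_threshold_current(p, 5000.0, t_window=20.0, tol_rel=1e-3)
        sweep = np.linspace(0.8 * th, 1.2 * th, 161)
        spk = _hh_single_spikes(p, np.full(sweep.size, 5000.0), sweep,
                                20.0, 0.01)
        brute = sweep[np.nonzero(spk)[0][0]]
        assert th == pytest.approx(brute, rel=3e-3)

    def test_unrecruitable_sentinel(self):
        p = HHParams(surface_areas=(2000.0,))
        th = hh_threshold_current(p, 2000.0, i_max=1e-6)
        assert th == UNRECRUITABLE


class TestErrors:
    def test_unknown_population_reference(self, default_circuit):
        proto = ProtocolSpec(kind="current_step",
                             injections=(("Mauthner", "left", 0, 1.0, 0, 10),))
        with pytest.raises(ConfigurationError):
            NetworkEngine(default_circuit).run(proto, t_end=5.0)

    def test_dt_bound(self, default_circuit):
        with pytest.raises(ConfigurationError):
            NetworkEngine(default_circuit, dt=0.05)
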