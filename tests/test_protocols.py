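"""Stimulation protocols: recruitment, EPSP/IPSP calibration, grids."""

import numpy as np
import pytest

from mauthnet import NetworkEngine, build_circuit
from mauthnet.errors import ConfigurationError
from mauthnet.protocols import (
    afferent_thresholds,
    check_ff_recruitment,
    drive_protocol,
    measure_epsp,
    measure_ipsp,
    peak_conductance_ratio,
    predicted_recruited_count,
    recruit_afferents,
    run_grid,
    stimulus_grid,
    strength_full,
    unit_current,
)


class TestRecruitment:
    def test_zero_strength_recruits_nothing(self, default_circuit):
        assert predicted_recruited_count(default_circuit, 0.0) == 0
        currents = recruit_afferents(default_circuit, 0.0, "left")
        assert np.all(currents == 0.0)

    def test_unit_strength_recruits_smallest(self, default_circuit):
        assert predicted_recruited_count(default_circuit, 1.0) == 1

    def test_full_strength_recruits_all(self, default_circuit):
        s_full = strength_full(default_circuit)
        assert predicted_recruited_count(default_circuit, s_full) == 30
        # in-network check against the threshold-table oracle
        sweep = run_grid(default_circuit,
                         stimulus_grid(default_circuit, n=2,
                                       s_max=1.001 * s_full))
        assert sweep.recruited_left[1, 0] == 30

    def test_recruitment_curve_is_a_30_step_function(self, default_circuit):
        th = afferent_thresholds(default_circuit)
        s = np.linspace(0, 1.05 * strength_full(default_circuit), 2000)
        counts = predicted_recruited_count(default_circuit, s)
        assert np.all(np.diff(counts) >= 0)
        assert set(np.unique(counts)) == set(range(31))
        # right-continuity: at each threshold the count includes that cell
        jumps = th / th[0]
        at_jumps = predicted_recruited_count(default_circuit, jumps)
        assert np.array_equal(at_jumps, np.arange(1, 31))

    def test_negative_strength_errors(self, default_circuit):
        with pytest.raises(ConfigurationError):
            recruit_afferents(default_circuit, -1.0, "left")
        with pytest.raises(ConfigurationError):
            drive_protocol(default_circuit, -1.0, 0.0)

    def test_recruitment_is_deterministic(self, default_circuit):
        a = predicted_recruited_count(default_circuit,
                                      np.linspace(0, 12, 50))
        b = predicted_recruited_count(default_circuit,
                                      np.linspace(0, 12, 50))
        assert np.array_equal(a, b)

    def test_ff_pairing_calibration(self, default_circuit):
        report = check_ff_recruitment(default_circuit)
        assert report["ff_recruited"] >= 1


class TestEPSP:
    def test_gap_component_has_no_synaptic_delay(self, default_circuit):
        rec = measure_epsp(default_circuit, zero_glutamate=True)
        v = rec.v("M", "left")
        first_aud = np.nanmin([s[0] if len(s) else np.nan
                               for s in rec.spikes[("auditory", "left")]])
        # the electrical EPSP starts rising well before the 0.7 ms
        # glutamatergic delay could deliver anything
        rising = np.nonzero(v - v[0] > 0.02)[0]
        assert rising.size and rec.t[rising[0]] < first_aud + 0.5
        assert (v - v[0]).max() > 0.1

    def test_glutamate_component_lags_by_its_delay(self, default_circuit):
        rec = measure_epsp(default_circuit, zero_gap=True)
        g = rec.conductances["auditory.left->M.left:glutamate"][0]
        first_aud = np.nanmin([s[0] if len(s) else np.nan
                               for s in rec.spikes[("auditory", "left")]])
        t_on = rec.t[np.nonzero(g > 0)[0][0]]
        assert t_on - first_aud == pytest.approx(0.7, abs=rec.dt + 1e-9)

    def test_driving_force_sublinearity(self, default_circuit):
        # doubling both conductances less than doubles the peak EPSP
        # (compared at half vs full strength so both stay subthreshold)
        halved = build_circuit(group_overrides={
            "auditory.left->M.left:gap": {"g_gap": 7.5},
            "auditory.left->M.left:glutamate": {"g_peak": 6.0}})
        rec_half = measure_epsp(halved)
        rec_full = measure_epsp(default_circuit)
        peak_half = rec_half.v("M", "left").max() - rec_half.v("M", "left")[0]
        peak_full = rec_full.v("M", "left").max() - rec_full.v("M", "left")[0]
        assert peak_half < peak_full < 2.0 * peak_half


@pytest.fixture(scope="module")
def exp(default_circuit):
    return measure_ipsp(default_circuit, [-1.5, -1.0, -0.5, 0.0, 0.5, 1.0])


class TestIPSP:
    def test_sign_flips_across_the_reversal(self, exp):
        from mauthnet.ephys_fitting import ipsp_amplitudes

        holds, amps = ipsp_amplitudes(exp)
        # below ECl (-75): depolarizing; above: hyperpolarizing
        assert np.all(amps[holds < -75.5] > 0)
        assert np.all(amps[holds > -74.5] < 0)

    def test_amplitude_is_linear_in_holding_potential(self, exp):
        from mauthnet.ephys_fitting import estimate_ecl

        diag = {}
        estimate_ecl(exp, diagnostics=diag)
        assert diag["r_squared"] > 0.999

    def test_contra_ipsi_conductance_ratio(self, exp):
        assert peak_conductance_ratio(exp) == pytest.approx(2.5, rel=1e-12)

    def test_suprathreshold_holding_is_flagged(self, default_circuit):
        exp = measure_ipsp(default_circuit, [3.0])  # +30 mV: above threshold
        assert 3.0 in exp.flagged


class TestGrid:
    def test_grid_covers_recruitment_range(self, default_circuit):
        grid = stimulus_grid(default_circuit, n=21)
        assert grid.strengths_left[0] == 0.0
        assert grid.strengths_left[-1] >= strength_full(default_circuit)
        assert np.all(np.diff(grid.strengths_left) > 0)

    def test_unit_current_is_smallest_threshold(self, default_circuit):
        th = afferent_thresholds(default_circuit)
        assert unit_current(default_circuit) == pytest.approx(th[0])
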