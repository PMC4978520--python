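"""Synthetic-data generators and nonparametric tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mauthnet.errors import ConfigurationError, DegenerateDataError
from mauthnet.synthetic_stats import (
    BehaviorDataset,
    gen_behavior,
    gen_paired,
    laterality_test,
    latency_contrast,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(diffs):
    """Independent oracle: enumerate every sign assignment explicitly."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    dev_obs = abs(ranks[d > 0].sum() - mu)
    hits = total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        hits += abs(w - mu) >= dev_obs - 1e-9
    return hits / total


class TestWilcoxon:
    def test_textbook_example(self):
        r = wilcoxon_signed_rank([1, 2, 3], mode="exact")
        assert r.statistic == 6.0
        assert r.p_value == pytest.approx(0.25)

    def test_antisymmetric_data_gives_p_one(self):
        assert wilcoxon_signed_rank([4.0, -4.0],
                                    mode="exact").p_value == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-8, 8), min_size=2, max_size=8))
    def test_exact_mode_equals_brute_force_enumeration(self, diffs):
        d = np.asarray(diffs, dtype=float)
        if (d != 0).sum() < 2:
            return
        mine = wilcoxon_signed_rank(d, mode="exact").p_value
        assert mine == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_exact_mode_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(20):
            mags = rng.choice(np.arange(1, 13), size=9, replace=False)
            d = mags * rng.choice([-1.0, 1.0], size=9)
            mine = wilcoxon_signed_rank(d, mode="exact").p_value
            ref = sps.wilcoxon(d, alternative="two-sided",
                               mode="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_permutation_agrees_with_exact(self, rng):
        d = rng.integers(-6, 7, size=11).astype(float)
        d[d == 0] = 1.0
        exact = wilcoxon_signed_rank(d, mode="exact").p_value
        n_perm = 200_000
        perm = wilcoxon_signed_rank(d, mode="permutation", n_perm=n_perm,
                                    seed=5).p_value
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(perm - exact) < 3 * se + 2 / n_perm

    def test_approx_mode_is_close_for_moderate_n(self, rng):
        d = rng.normal(0.3, 1.0, size=18)
        exact = wilcoxon_signed_rank(d, mode="exact").p_value
        approx = wilcoxon_signed_rank(d, mode="approx").p_value
        assert approx == pytest.approx(exact, abs=0.03)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0], mode="exact")
        with pytest.raises(ConfigurationError):
            wilcoxon_signed_rank(np.ones(25), mode="exact")
        with pytest.raises(ConfigurationError):
            wilcoxon_signed_rank([1, 2], mode="banana")

    def test_pratt_zero_handling_ranks_zeros(self):
        # zeros raise the ranks of nonzero differences under Pratt
        drop = wilcoxon_signed_rank([0, 1, 2], mode="exact",
                                    zero_method="drop")
        pratt = wilcoxon_signed_rank([0, 1, 2], mode="exact",
                                     zero_method="pratt")
        assert pratt.statistic > drop.statistic


class TestPairedGenerator:
    def test_zero_effect_zero_spread_is_identity(self):
        d = gen_paired(50, mean_log_ratio=0.0, sd_log_ratio=0.0,
                       kind="boutons", seed=3)
        assert np.array_equal(d.ipsi, d.contra)

    def test_mean_ratio_converges_to_lognormal_mean(self):
        mlr, sd = math.log(2.44), 0.3
        d = gen_paired(300_000, mean_log_ratio=mlr, sd_log_ratio=sd,
                       kind="ipsp", seed=4)
        assert d.mean_ratio() == pytest.approx(
            2.44 * math.exp(sd**2 / 2), rel=0.01)

    def test_seed_reproducibility(self):
        a = gen_paired(40, seed=11)
        b = gen_paired(40, seed=11)
        assert np.array_equal(a.ipsi, b.ipsi)
        assert np.array_equal(a.contra, b.contra)

    def test_bouton_counts_are_nonnegative_integers(self):
        d = gen_paired(500, kind="boutons", seed=6)
        assert np.all(d.ipsi >= 1) and np.all(d.contra >= 0)
        assert np.all(d.ipsi == np.round(d.ipsi))

    def test_invalid_kind_errors(self):
        with pytest.raises(ConfigurationError):
            gen_paired(5, kind="spines", seed=0)

    def test_contralateral_bias_is_detected(self):
        # at the study scale (n=19 pairs) the bias is highly significant
        d = gen_paired(19, kind="ipsp", seed=7)
        r = wilcoxon_signed_rank(d, mode="exact")
        assert r.p_value < 0.001
        assert r.effect > 0


class TestBehaviorGenerator:
    def test_structure_and_determinism(self):
        a = gen_behavior(conditions=["sham"], n_fish=4, seed=9)
        b = gen_behavior(conditions=["sham"], n_fish=4, seed=9)
        assert a.latency_trials.equals(b.latency_trials)
        assert len(a.latency_trials) == 4 * 2 * 5
        assert len(a.direction_trials) == 4 * 10
        assert (a.latency_trials["latency_ms"] > 0).all()

    def test_parameter_recovery_at_large_n(self):
        big = gen_behavior(conditions=["lateral_glycine_FF"], n_fish=400,
                           trials_per_side=50,
                           direction_trials_per_fish=50, seed=12)
        frac = big.direction_trials["initiated_lesioned"].mean()
        assert frac == pytest.approx(0.25, abs=0.01)
        med = big.latency_trials.groupby("side")["latency_ms"].median()
        assert med["lesioned"] == pytest.approx(6.0, rel=0.02)
        assert med["unlesioned"] == pytest.approx(10.0, rel=0.02)

    def test_unknown_condition_errors(self):
        with pytest.raises(ConfigurationError):
            gen_behavior(conditions=["spinalized"], seed=0)


class TestLateralityTest:
    def test_mauthner_killed_like_condition(self):
        b = gen_behavior(conditions=["mauthner_killed"], seed=21)
        r = laterality_test(b, "mauthner_killed")
        assert r.effect == pytest.approx(0.0, abs=0.05)
        assert r.p_value < 1e-6

    def test_single_fish_warns_and_falls_back_to_binomial(self):
        b = gen_behavior(conditions=["sham"], n_fish=1, seed=22)
        with pytest.warns(UserWarning):
            r = laterality_test(b, "sham")
        assert r.null == "exact_binomial_pooled"

    def test_missing_condition_errors(self):
        b = gen_behavior(conditions=["sham"], seed=23)
        with pytest.raises(ConfigurationError):
            laterality_test(b, "mauthner_killed")


class TestLatencyContrast:
    def test_scale_invariance_on_the_log_scale(self):
        b = gen_behavior(conditions=["lateral_glycine_FF"], seed=31)
        r1 = latency_contrast(b)[0]
        scaled = BehaviorDataset(
            latency_trials=b.latency_trials.assign(
                latency_ms=b.latency_trials["latency_ms"] * 7.5),
            direction_trials=b.direction_trials, params=b.params, seed=b.seed)
        r2 = latency_contrast(scaled)[0]
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_holm_correction_across_conditions(self):
        b = gen_behavior(seed=32)
        results = latency_contrast(b)
        assert len(results) == 5
        for r in results:
            assert r.extras["p_adjusted"] >= r.p_value - 1e-12

    def test_power_at_study_scale_effect(self):
        """6 vs 10 ms medians at ~27 trials/side: power above one half."""
        rej = 0
        reps = 120
        for i in range(reps):
            b = gen_behavior(conditions=["lateral_glycine_FF"], n_fish=6,
                             trials_per_side=5, seed=40_000 + i)
            if latency_contrast(b)[0].p_value <= 0.05:
                rej += 1
        assert rej / reps > 0.5

    def test_one_sided_condition_is_excluded_with_warning(self):
        b = gen_behavior(conditions=["sham"], seed=33)
        lone = b.latency_trials[b.latency_trials["side"] == "lesioned"]
        crippled = BehaviorDataset(latency_trials=lone,
                                   direction_trials=b.direction_trials,
                                   params=b.params, seed=b.seed)
        with pytest.warns(UserWarning):
            assert latency_contrast(crippled) == []
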