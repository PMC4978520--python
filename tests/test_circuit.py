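"""Circuit construction: parameter-table fidelity, variants, ablations."""

import numpy as np
import pytest

from mauthnet import AblationSpec, build_circuit, mirror_check
from mauthnet.circuit import CircuitVariant, FULL_CIRCUIT
from mauthnet.errors import AblationError, ConfigurationError


class TestDefaultBuild:
    def test_population_sizes(self, default_circuit):
        for side in ("left", "right"):
            assert default_circuit.population("M", side).n == 1
            assert default_circuit.population("FF", side).n == 30
            assert default_circuit.population("auditory", side).n == 30

    def test_afferent_area_gradient(self, default_circuit):
        areas = default_circuit.population("auditory", "left").params.surface_areas
        assert areas[0] == 2000.0 and areas[-1] == 20000.0
        assert np.allclose(np.diff(areas), areas[1] - areas[0])

    def test_connectivity_matches_parameter_table(self, default_circuit):
        """Golden check of every group's conductance, delay, tau, pattern."""
        expected = {
            ("FF.left->M.left:glycine", 25.0, 0.3, 2.0, -75.0, "all_to_one"),
            ("FF.left->M.right:glycine", 62.5, 0.3, 2.0, -75.0, "all_to_one"),
            ("FF.left->FF.right:glycine", 12.0, 0.3, 2.0, -75.0, "all_to_all"),
            ("auditory.left->M.left:glutamate", 12.0, 0.7, 2.0, 0.0,
             "all_to_one"),
        }
        got = {(s.name, s.g_peak, s.delay, s.tau_decay, s.E_rev, s.pattern)
               for s in default_circuit.synapses}
        assert expected <= got
        assert len(default_circuit.synapses) == 8  # 4 chemical groups/side
        gaps = {g.name: g for g in default_circuit.gap_junctions}
        assert len(gaps) == 4
        am = gaps["auditory.left->M.left:gap"]
        assert (am.g_gap, am.dendritic_tau, am.pattern, am.lumped) == (
            15.0, 0.4, "all_to_one", True)
        aff = gaps["auditory.right->FF.right:gap"]
        assert (aff.g_gap, aff.pattern, aff.lumped) == (10.0, "one_to_one",
                                                        False)

    def test_full_variant_group_count(self, default_circuit):
        # 6 groups per side, mirrored
        assert len(default_circuit.synapses) + len(
            default_circuit.gap_junctions) == 12

    def test_glycine_reversal_tracks_postsynaptic_ecl(self, default_circuit):
        for s in default_circuit.synapses:
            if s.transmitter == "glycine":
                post = default_circuit.population(*s.post_pop)
                assert s.E_rev == post.params.ECl


class TestVariants:
    @pytest.mark.parametrize("variant, has_ipsi, contra_g, has_mutual", [
        (CircuitVariant.IPSI_ONLY, True, None, False),
        (CircuitVariant.SYM_BILATERAL, True, 25.0, False),
        (CircuitVariant.BIASED_BILATERAL, True, 62.5, False),
        (CircuitVariant.SYM_BILATERAL_MUTUAL, True, 25.0, True),
        (CircuitVariant.BIASED_BILATERAL_MUTUAL, True, 62.5, True),
        (CircuitVariant.CONTRA_ONLY_WEAK, False, 25.0, False),
        (CircuitVariant.CONTRA_ONLY_STRONG, False, 62.5, False),
    ])
    def test_variant_synapse_edits(self, variant, has_ipsi, contra_g,
                                   has_mutual):
        circ = build_circuit(variant)
        by_name = {s.name: s for s in circ.synapses}
        assert ("FF.left->M.left:glycine" in by_name) == has_ipsi
        contra = by_name.get("FF.left->M.right:glycine")
        if contra_g is None:
            assert contra is None
        else:
            assert contra is not None and contra.g_peak == contra_g
        assert ("FF.left->FF.right:glycine" in by_name) == has_mutual

    def test_variant_edits_touch_only_ff_groups(self):
        """Variants differ from the full circuit only in FF->M / FF->FF."""
        full = {s.name: (s.g_peak, s.pattern) for s in
                build_circuit(FULL_CIRCUIT).synapses}
        full_gaps = {g.name: g.g_gap for g in
                     build_circuit(FULL_CIRCUIT).gap_junctions}
        for v in CircuitVariant:
            circ = build_circuit(v)
            assert {g.name: g.g_gap for g in circ.gap_junctions} == full_gaps
            for s in circ.synapses:
                if s.name in full and (s.g_peak, s.pattern) != full[s.name]:
                    assert s.pre_pop[0] == "FF"
                elif s.name not in full:
                    assert s.pre_pop[0] == "FF"

    def test_contra_strength_is_a_ratio_of_ipsi(self):
        circ = build_circuit(overrides={"synapses": {"ff_ipsi_m":
                                                     {"g_peak": 30.0}}})
        by_name = {s.name: s for s in circ.synapses}
        assert by_name["FF.left->M.right:glycine"].g_peak == pytest.approx(75.0)

    def test_unknown_variant_and_override_errors(self):
        with pytest.raises(ConfigurationError):
            build_circuit("no_such_variant")
        with pytest.raises(ConfigurationError):
            build_circuit(overrides={"lif": {"M": {"Rx": 1}}})
        with pytest.raises(ConfigurationError):
            build_circuit(group_overrides={"no.such->group:here":
                                           {"g_peak": 1.0}})


class TestAblations:
    def test_full_removal_drops_cells_and_connections(self):
        circ = build_circuit(
            ablations=[AblationSpec("FF_pool", "right", "all")])
        assert circ.population("FF", "right").n == 0
        for g in (*circ.synapses, *circ.gap_junctions):
            assert ("FF", "right") not in (g.pre_pop, g.post_pop)
        # the intact side keeps its groups
        assert any(s.pre_pop == ("FF", "left") for s in circ.synapses)

    def test_half_removal_takes_even_positions(self):
        circ = build_circuit(
            ablations=[AblationSpec("FF_pool", "right", "half")])
        pop = circ.population("FF", "right")
        assert pop.n == 15
        assert pop.cell_ids == tuple(range(1, 30, 2))

    def test_random_half_is_seeded(self):
        a = AblationSpec("FF_pool", "left", "half", method="random", seed=7)
        ids1 = build_circuit(ablations=[a]).population("FF", "left").cell_ids
        ids2 = build_circuit(ablations=[a]).population("FF", "left").cell_ids
        assert ids1 == ids2 and len(ids1) == 15

    def test_repeated_or_impossible_ablation_errors(self):
        a = AblationSpec("FF_pool", "right", "all")
        with pytest.raises(AblationError):
            build_circuit(ablations=[a, a])
        with pytest.raises(AblationError):
            build_circuit(ablations=[
                AblationSpec("FF_pool", "right", "all"),
                AblationSpec("FF_pool", "right", "half")])

    def test_mauthner_ablation(self):
        circ = build_circuit(ablations=[AblationSpec("Mauthner", "left",
                                                     "all")])
        assert circ.population("M", "left").n == 0
        assert all(g.post_pop != ("M", "left") for g in circ.synapses)


class TestMirror:
    def test_unablated_circuit_is_mirror_symmetric(self, default_circuit):
        assert mirror_check(default_circuit)

    def test_ablation_breaks_mirror_symmetry(self):
        circ = build_circuit(
            ablations=[AblationSpec("FF_pool", "right", "all")])
        assert not mirror_check(circ)

    def test_one_sided_override_breaks_mirror_symmetry(self):
        circ = build_circuit(group_overrides={
            "FF.left->M.left:glycine": {"g_peak": 30.0}})
        assert not mirror_check(circ)


class TestSerialization:
    def test_yaml_roundtrip(self, tmp_path, default_circuit):
        path = tmp_path / "circuit.yaml"
        default_circuit.save(path)
        loaded = type(default_circuit).load(path)
        assert loaded.canonical() == default_circuit.canonical()

    def test_shipped_default_config_matches_builtins(self):
        from importlib import resources

        import yaml

        from mauthnet.circuit import default_config

        with resources.files("mauthnet").joinpath(
                "data/default_circuit.yaml").open() as fh:
            doc = yaml.safe_load(fh)
        assert doc["config"] == default_config()
        assert doc["variant"] == FULL_CIRCUIT.value

    def test_connectivity_table_shape(self, default_circuit):
        tab = default_circuit.connectivity_table()
        assert len(tab) == 12
        assert set(tab["kind"]) == {"glycine", "glutamate", "gap"}
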