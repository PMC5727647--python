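"""Normal/tumor coordination comparison: paired t, edge counts, clustering
and divergence ranking."""

import numpy as np
import pandas as pd
import pytest

import methcoord as mc
from conftest import paired_t_oracle
from methcoord.differential import paired_delta_t, significance_tier


def _panel_from_r(group, r_values, genes=("A", "B", "C")):
    """Hand-built CorrelationPanel with prescribed r values."""
    pairs = mc.canonical_pairs(list(genes))
    frame = pd.DataFrame(
        {
            "gene_a": [a for a, _ in pairs],
            "gene_b": [b for _, b in pairs],
            "n": 50,
            "r": list(r_values),
            "p": 0.01,
            "p_adj": 0.02,
            "significant_positive": [r > 0.3 for r in r_values],
        }
    )
    return mc.CorrelationPanel(group=group, genes=list(genes), pairs=frame)


class TestPairedComparison:
    def test_identical_conditions_give_null_identity(self):
        normals = [_panel_from_r(f"t{i}/normal", [0.5, 0.2, 0.4]) for i in range(3)]
        tumors = [_panel_from_r(f"t{i}/tumor", [0.5, 0.2, 0.4]) for i in range(3)]
        res = mc.paired_pair_comparison(normals, tumors)
        assert (res["t_statistic"] == 0).all()
        assert (res["p"] == 1).all()
        assert (res["significance_tier"] == "ns").all()

    def test_matches_closed_form_on_hand_example(self):
        diffs = [0.3, 0.1, 0.2, 0.4]
        t, p = paired_delta_t(np.array(diffs))
        t_ref, p_ref = paired_t_oracle(diffs)
        assert t == pytest.approx(t_ref)          # = 0.25 / (0.1291/2) ~ 3.873
        assert p == pytest.approx(p_ref)
        assert t == pytest.approx(3.873, abs=1e-3)

    def test_agrees_with_oracle_on_random_difference_vectors(self, rng):
        for _ in range(1000):
            d = rng.normal(scale=0.3, size=int(rng.integers(3, 15)))
            t, p = paired_delta_t(d)
            t_ref, p_ref = paired_t_oracle(d)
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_constant_nonzero_differences_are_degenerate(self):
        with pytest.raises(mc.DegenerateTestError):
            paired_delta_t(np.array([0.2, 0.2, 0.2]))

    def test_swapping_conditions_negates_t_and_delta(self, matched_panels):
        normal, tumor = matched_panels
        fwd = mc.paired_pair_comparison(normal, tumor)
        rev = mc.paired_pair_comparison(tumor, normal)
        np.testing.assert_allclose(fwd["mean_delta"], -rev["mean_delta"])
        np.testing.assert_allclose(fwd["t_statistic"], -rev["t_statistic"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_tissue_mismatch_is_named_error(self):
        normals = [_panel_from_r("liver/normal", [0.5, 0.2, 0.4])]
        tumors = [_panel_from_r("lung/tumor", [0.1, 0.0, 0.2])]
        with pytest.raises(mc.ValidationError, match="liver|lung"):
            mc.paired_pair_comparison(normals, tumors)

    def test_planted_coordination_loss_detected(self, matched_panels):
        normal, tumor = matched_panels
        res = mc.paired_pair_comparison(normal, tumor)
        assert (res["p"] < 0.05).all()
        assert (res["mean_delta"] > 0.3).all()

    @pytest.mark.parametrize(
        "p,tier", [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "ns"),
                   (0.05, "ns"), (0.01, "*"), (0.001, "**")],
    )
    def test_significance_tiers_use_strict_cutoffs(self, p, tier):
        assert significance_tier(p) == tier


class TestEdgeConnectivity:
    def test_all_tissues_higher_gives_max_count(self):
        normals = [_panel_from_r(f"t{i}/normal", [0.6, 0.5, 0.4]) for i in range(12)]
        tumors = [_panel_from_r(f"t{i}/tumor", [0.1, 0.0, 0.2]) for i in range(12)]
        edges = mc.edge_connectivity(normals, tumors)
        assert (edges["count"] == 12).all()
        assert (edges["total_tissues"] == 12).all()

    def test_ties_count_zero(self):
        normals = [_panel_from_r(f"t{i}/normal", [0.5, 0.2, 0.4]) for i in range(5)]
        tumors = [_panel_from_r(f"t{i}/tumor", [0.5, 0.2, 0.4]) for i in range(5)]
        assert (mc.edge_connectivity(normals, tumors)["count"] == 0).all()

    def test_mixed_strict_wins_counted_exactly(self, rng):
        wins = [1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0]  # 7 of 12
        normals, tumors = [], []
        for i, w in enumerate(wins):
            rn = [0.5, 0.3, 0.1]
            rt = [0.5 - 0.2 * w, 0.3, 0.1]  # only pair A-B moves
            normals.append(_panel_from_r(f"t{i}/normal", rn))
            tumors.append(_panel_from_r(f"t{i}/tumor", rt))
        edges = mc.edge_connectivity(normals, tumors)
        assert edges.loc["A-B", "count"] == 7
        assert edges.loc["A-C", "count"] == 0

    def test_swap_maps_count_to_complement_excluding_ties(self, matched_panels):
        normal, tumor = matched_panels
        fwd = mc.edge_connectivity(normal, tumor)["count"]
        rev = mc.edge_connectivity(tumor, normal)["count"]
        assert ((fwd + rev) <= 4).all()  # ties excluded from both
        assert ((fwd + rev) >= 0).all()

    def test_connectivity_graph_edges(self):
        normals = [_panel_from_r(f"t{i}/normal", [0.6, 0.5, 0.4]) for i in range(3)]
        tumors = [_panel_from_r(f"t{i}/tumor", [0.1, 0.0, 0.2]) for i in range(3)]
        g = mc.connectivity_graph(mc.edge_connectivity(normals, tumors))
        assert g["A"]["B"]["weight"] == 3
        assert set(g.nodes) == {"A", "B", "C"}


class TestClusterProfiles:
    def _profiles(self, vectors, labels):
        idx = [f"p{i}" for i in range(len(vectors[0]))]
        return [
            mc.CoordinationProfile(tissue=lab, condition="normal",
                                   r_vector=pd.Series(v, index=idx))
            for lab, v in zip(labels, vectors)
        ]

    def test_identical_profiles_merge_first_at_zero_height(self):
        profiles = self._profiles(
            [[0.5, 0.1, 0.3], [0.5, 0.1, 0.3], [0.9, 0.8, 0.7], [-0.2, 0.0, 0.1]],
            ["a", "b", "c", "d"],
        )
        result = mc.cluster_profiles(profiles)
        assert result.linkage[0, 2] == pytest.approx(0.0)
        assert {int(result.linkage[0, 0]), int(result.linkage[0, 1])} == {0, 1}

    def test_planted_blocks_separate_at_two_cluster_cut(self, rng):
        block1 = [np.full(21, 0.6) + rng.normal(0, 0.03, 21) for _ in range(12)]
        block2 = [np.full(21, 0.1) + rng.normal(0, 0.03, 21) for _ in range(12)]
        labels = [f"n{i}" for i in range(12)] + [f"t{i}" for i in range(12)]
        result = mc.cluster_profiles(self._profiles(block1 + block2, labels))
        cut = result.cut(2)
        normal_clusters = {cut[f"n{i}_normal"] for i in range(12)}
        tumor_clusters = {cut[f"t{i}_normal"] for i in range(12)}
        assert len(normal_clusters) == 1 and len(tumor_clusters) == 1
        assert normal_clusters != tumor_clusters

    def test_row_permutation_preserves_merge_heights(self, rng):
        vectors = [rng.uniform(-1, 1, size=5) for _ in range(8)]
        labels = [f"t{i}" for i in range(8)]
        base = mc.cluster_profiles(self._profiles(vectors, labels))
        perm = rng.permutation(8)
        shuffled = mc.cluster_profiles(
            self._profiles([vectors[i] for i in perm], [labels[i] for i in perm])
        )
        np.testing.assert_allclose(
            np.sort(base.linkage[:, 2]), np.sort(shuffled.linkage[:, 2])
        )

    def test_length_mismatch_is_error(self):
        profiles = self._profiles([[0.1, 0.2]], ["a"])
        profiles.append(
            mc.CoordinationProfile("b", "tumor", pd.Series([0.1, 0.2, 0.3]))
        )
        with pytest.raises(mc.ValidationError, match="length"):
            mc.cluster_profiles(profiles)


class TestTopDivergentPairs:
    def _results(self, deltas, ps=None):
        ps = ps or [0.01] * len(deltas)
        return pd.DataFrame(
            {"mean_delta": deltas, "p": ps},
            index=[f"pair{i}" for i in range(len(deltas))],
        )

    def test_full_k_gives_total_ordering(self):
        res = self._results([0.1, 0.5, 0.3])
        ranked = mc.top_divergent_pairs(res, k=3)
        assert ranked["mean_delta"].tolist() == [0.5, 0.3, 0.1]

    def test_planted_dominant_pair_ranked_first(self):
        res = self._results([0.0, 0.0, 0.5, 0.0])
        assert mc.top_divergent_pairs(res, k=1).index[0] == "pair2"

    def test_top3_recovers_planted_deltas(self):
        res = self._results([0.5, 0.0, 0.4, 0.0, 0.3, 0.0])
        top = mc.top_divergent_pairs(res, k=3)
        assert set(top.index) == {"pair0", "pair2", "pair4"}
        assert top["mean_delta"].tolist() == [0.5, 0.4, 0.3]

    def test_ties_break_by_smaller_p_then_input_order(self):
        res = self._results([0.3, 0.3, 0.3], ps=[0.05, 0.001, 0.001])
        ranked = mc.top_divergent_pairs(res, k=3)
        assert ranked.index.tolist() == ["pair1", "pair2", "pair0"]

    @pytest.mark.parametrize("k", [0, -1, 5])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(mc.ValidationError):
            mc.top_divergent_pairs(self._results([0.1, 0.2]), k=k)


class TestGroupPanelComparison:
    def test_self_comparison_gives_zero_deltas(self):
        panel = _panel_from_r("blood/normal", [0.5, 0.2, 0.4])
        out = mc.group_panel_comparison(panel, panel)
        assert (out["delta"] == 0).all()
        assert not out["sign_flip"].any()

    def test_sign_flip_flagged(self):
        a = _panel_from_r("blood/normal", [0.4, 0.2, 0.1])
        b = _panel_from_r("leukemia/tumor", [-0.2, 0.3, 0.1])
        out = mc.group_panel_comparison(a, b)
        assert out.loc["A-B", "delta"] == pytest.approx(0.6)
        assert bool(out.loc["A-B", "sign_flip"])
        assert not bool(out.loc["A-C", "sign_flip"])

    def test_simulated_two_group_delta_within_fisher_bound(self):
        cfg = mc.SimulationConfig(
            tissues=("blood", "leukemia"),
            conditions=("normal", "tumor"),
            samples_per_group=300,
            target_correlation={
                ("blood", "normal"): mc.compound_symmetric(7, 0.5),
                ("leukemia", "tumor"): mc.compound_symmetric(7, -0.1),
            },
            seed=23,
        )
        expr = mc.simulate_study(cfg)
        genes = list(cfg.panel_genes)
        a = mc.build_panel(expr, genes, tissue="blood", condition="normal")
        b = mc.build_panel(expr, genes, tissue="leukemia", condition="tumor")
        out = mc.group_panel_comparison(a, b)
        assert out["delta"].mean() == pytest.approx(0.6, abs=0.15)

    def test_panel_mismatch_is_error(self):
        a = _panel_from_r("x/normal", [0.1, 0.2, 0.3], genes=("A", "B", "C"))
        b = _panel_from_r("y/tumor", [0.1, 0.2, 0.3], genes=("A", "B", "D"))
        with pytest.raises(mc.ValidationError, match="panel"):
            mc.group_panel_comparison(a, b)
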