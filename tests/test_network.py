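"""Equal-frequency discretization, plug-in MI, and quantile thresholding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdremir.io import ExpressionMatrix
from cdremir.network import (
    BipartiteNetwork,
    ScoredPairs,
    default_bin_count,
    discretize_equal_frequency,
    mutual_information,
    score_all_pairs,
    threshold_by_quantile,
    write_edge_list,
    read_edge_list,
)

from _oracles import mi_plugin_oracle


class TestDiscretize:
    def test_distinct_values_split_evenly(self):
        np.testing.assert_array_equal(
            discretize_equal_frequency([1, 2, 3, 4], 2), [0, 0, 1, 1]
        )

    def test_ties_share_one_bin(self):
        labels = discretize_equal_frequency([5, 5, 5, 9], 2)
        np.testing.assert_array_equal(labels, [0, 0, 0, 1])

    def test_labels_range(self, rng):
        x = rng.normal(size=47)
        labels = discretize_equal_frequency(x, 5)
        assert set(labels) == set(range(5))
        sizes = np.bincount(labels)
        assert sizes.max() - sizes.min() <= 1

    def test_monotone_transform_gives_identical_labels(self, rng):
        x = rng.lognormal(size=60)
        a = discretize_equal_frequency(x, 6)
        b = discretize_equal_frequency(np.log(x), 6)
        c = discretize_equal_frequency(x**3, 6)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a, c)

    @pytest.mark.parametrize("bad_bins", [0, 1, 11])
    def test_bin_count_bounds(self, bad_bins):
        with pytest.raises(ValueError):
            discretize_equal_frequency(list(range(10)), bad_bins)


class TestMutualInformation:
    def test_perfect_dependence_is_one_bit(self):
        assert mutual_information([1, 2, 3, 4], [1, 2, 3, 4], 2) == pytest.approx(1.0)

    def test_label_independence_is_zero(self):
        assert mutual_information([1, 2, 3, 4], [1, 8, 2, 7], 2) == 0.0

    def test_self_mi_is_log2_bins(self, rng):
        x = rng.normal(size=60)
        for b in (2, 3, 5, 6):
            assert mutual_information(x, x, b) == pytest.approx(math.log2(b))

    def test_symmetry(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert mutual_information(x, y, 5) == pytest.approx(
            mutual_information(y, x, 5), rel=1e-12
        )

    def test_matches_independent_plugin_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=50), 0.5 * rng.normal(size=50)
            mi = mutual_information(x, y, 5)
            assert mi == pytest.approx(mi_plugin_oracle(x, y, 5), rel=1e-12, abs=1e-12)

    def test_monotone_invariance(self, rng):
        x, y = rng.lognormal(size=40), rng.lognormal(size=40)
        base = mutual_information(x, y, 5)
        assert mutual_information(np.log(x), y, 5) == pytest.approx(base, rel=1e-12)
        assert mutual_information(x, np.sqrt(y), 5) == pytest.approx(base, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mutual_information([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2, 3, 4], [1, 2, 3], 2)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=40, unique=True),
           st.integers(2, 4))
    def test_nonnegative_for_arbitrary_input(self, xs, b):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        ys = rng.permutation(xs)
        assert mutual_information(xs, ys, b) >= 0.0


def _expr(values, prefix, layer):
    n_t, n_s = np.asarray(values).shape
    return ExpressionMatrix(
        layer=layer,
        data=pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(n_t)],
            columns=[f"s{j}" for j in range(n_s)],
        ),
    )


class TestScoreAllPairs:
    def test_cardinality(self, rng):
        mir = _expr(rng.lognormal(size=(3, 20)), "m", "miR")
        gene = _expr(rng.lognormal(size=(5, 20)), "g", "gene")
        scores = score_all_pairs(mir, gene, n_bins=4)
        assert scores.total_pair_count == 15

    def test_constant_transcripts_dropped(self, rng):
        gvals = rng.lognormal(size=(5, 20))
        gvals[2] = 1.0
        mir = _expr(rng.lognormal(size=(3, 20)), "m", "miR")
        gene = _expr(gvals, "g", "gene")
        scores = score_all_pairs(mir, gene, n_bins=4)
        assert scores.total_pair_count == 12
        assert "g2" not in scores.gene_ids

    def test_sample_mismatch_rejected(self, rng):
        mir = _expr(rng.lognormal(size=(2, 10)), "m", "miR")
        gene = _expr(rng.lognormal(size=(2, 10)), "g", "gene")
        gene = ExpressionMatrix(layer="gene", data=gene.data.iloc[:, ::-1])
        with pytest.raises(ValueError, match="sample"):
            score_all_pairs(mir, gene)

    def test_matches_pairwise_mutual_information(self, rng):
        mir = _expr(rng.lognormal(size=(4, 30)), "m", "miR")
        gene = _expr(rng.lognormal(size=(6, 30)), "g", "gene")
        scores = score_all_pairs(mir, gene, n_bins=5)
        for i, m in enumerate(scores.mir_ids):
            for j, g in enumerate(scores.gene_ids):
                expected = mutual_information(
                    mir.data.loc[m], gene.data.loc[g], n_bins=5
                )
                assert scores.scores[i, j] == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_default_bin_count_is_sqrt_n(self):
        assert default_bin_count(100) == 10
        assert default_bin_count(5) == 2


def _scored(score_matrix):
    m, g = np.asarray(score_matrix).shape
    return ScoredPairs(
        mir_ids=tuple(f"m{i}" for i in range(m)),
        gene_ids=tuple(f"g{j}" for j in range(g)),
        scores=np.asarray(score_matrix, dtype=float),
        n_bins=2,
    )


class TestThreshold:
    def test_distinct_scores_give_ceil_count(self, rng):
        scores = _scored(rng.permutation(np.linspace(0.01, 1, 100)).reshape(10, 10))
        net = threshold_by_quantile(scores, q=0.95)
        assert net.n_edges == math.ceil(0.05 * 100)

    def test_ties_at_threshold_all_kept(self):
        scores = _scored([[5.0, 4.0], [4.0, 3.0]])
        # m = ceil(0.5*4) = 2, threshold = 4, both 4s kept
        net = threshold_by_quantile(scores, q=0.5)
        assert net.n_edges == 3
        assert net.threshold_value == 4.0

    def test_all_edges_cross_layer_and_weighted_above_threshold(self, rng):
        scores = _scored(rng.random((6, 8)))
        net = threshold_by_quantile(scores, q=0.9)
        mirs, genes = set(net.mir_nodes), set(net.gene_nodes)
        for m, g, w in net.edges:
            assert m in mirs and g in genes
            assert w >= net.threshold_value

    def test_isolated_nodes_kept_in_node_sets(self, rng):
        scores = _scored(rng.random((5, 5)))
        net = threshold_by_quantile(scores, q=0.99)
        assert len(net.mir_nodes) == 5 and len(net.gene_nodes) == 5
        assert net.n_edges == 1

    def test_all_equal_scores_warns_and_keeps_everything(self):
        scores = _scored(np.full((3, 3), 0.7))
        with pytest.warns(UserWarning, match="every pair"):
            net = threshold_by_quantile(scores, q=0.9)
        assert net.n_edges == 9

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_domain(self, q):
        with pytest.raises(ValueError):
            threshold_by_quantile(_scored([[1.0]]), q=q)

    def test_within_layer_edge_rejected_on_construction(self):
        with pytest.raises(ValueError):
            BipartiteNetwork(
                mir_nodes=("m1", "m2"),
                gene_nodes=("g1",),
                edges=(("m1", "m2", 1.0),),
                threshold_value=0.0,
                quantile=0.5,
            )

    def test_edge_list_round_trip(self, tmp_path, rng):
        scores = _scored(rng.random((4, 4)))
        net = threshold_by_quantile(scores, q=0.8)
        write_edge_list(net, tmp_path / "edges.tsv")
        back = read_edge_list(
            tmp_path / "edges.tsv",
            mir_nodes=net.mir_nodes,
            gene_nodes=net.gene_nodes,
        )
        for (m1, g1, w1), (m2, g2, w2) in zip(sorted(back.edges), sorted(net.edges)):
            assert (m1, g1) == (m2, g2)
            assert w1 == pytest.approx(w2, rel=1e-9)
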