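"""Wang S-values and similarity, term clustering, representative selection."""

import numpy as np
import pandas as pd
import pytest

from cdremir.semantic import (
    DEFAULT_EDGE_WEIGHTS,
    FunctionGroup,
    OntologyDAG,
    aggregate_function_groups,
    cluster_terms,
    pairwise_similarity,
    read_ontology,
    select_representative,
    svalues,
    wang_similarity,
    write_ontology,
)

from _oracles import random_dag, svalues_max_over_paths


def _dag(parents):
    return OntologyDAG(parents=parents)


@pytest.fixture
def sibling_dag():
    """Root R with two is_a children A and B."""
    return _dag({"R": (), "A": (("R", "is_a"),), "B": (("R", "is_a"),)})


@pytest.fixture
def diamond_dag():
    """A -> {X, Y} -> R with mixed edge types."""
    return _dag(
        {
            "R": (),
            "X": (("R", "is_a"),),
            "Y": (("R", "part_of"),),
            "A": (("X", "part_of"), ("Y", "is_a")),
        }
    )


class TestSValues:
    def test_root_maps_to_itself(self, sibling_dag):
        assert svalues("R", sibling_dag) == {"R": 1.0}

    def test_single_chain(self):
        dag = _dag({"R": (), "A": (("R", "is_a"),)})
        assert svalues("A", dag) == {"A": 1.0, "R": 0.8}

    def test_diamond_takes_max_over_paths(self, diamond_dag):
        s = svalues("A", diamond_dag)
        # via X: 0.6 then 0.6*0.8 = 0.48; via Y: 0.8 then 0.8*0.6 = 0.48
        assert s == pytest.approx({"A": 1.0, "X": 0.6, "Y": 0.8, "R": 0.48})

    def test_term_absent_raises(self, sibling_dag):
        with pytest.raises(KeyError):
            svalues("Z", sibling_dag)

    def test_matches_max_over_paths_oracle_on_random_dags(self, rng):
        for _ in range(200):
            parents = random_dag(rng, int(rng.integers(2, 8)))
            dag = _dag(parents)
            term = list(parents)[int(rng.integers(len(parents)))]
            expected = svalues_max_over_paths(term, parents, DEFAULT_EDGE_WEIGHTS)
            got = svalues(term, dag)
            assert got.keys() == expected.keys()
            for t in expected:
                assert got[t] == pytest.approx(expected[t], rel=1e-12)


class TestWangSimilarity:
    def test_self_similarity_is_one(self, diamond_dag):
        for t in diamond_dag.terms:
            assert wang_similarity(t, t, diamond_dag) == 1.0

    def test_siblings_under_root(self, sibling_dag):
        # SV = 1.8 each, shared ancestor {R} contributes 0.8 + 0.8
        assert wang_similarity("A", "B", sibling_dag) == pytest.approx(4 / 9)

    def test_disconnected_components_score_zero(self):
        dag = _dag({"R1": (), "R2": (), "A": (("R1", "is_a"),), "B": (("R2", "is_a"),)})
        assert wang_similarity("A", "B", dag) == 0.0

    def test_symmetric_bounded_on_random_dags(self, rng):
        for _ in range(30):
            parents = random_dag(rng, 7)
            dag = _dag(parents)
            terms = list(parents)
            a, b = (terms[int(i)] for i in rng.integers(len(terms), size=2))
            s1, s2 = wang_similarity(a, b, dag), wang_similarity(b, a, dag)
            assert s1 == pytest.approx(s2, rel=1e-12)
            assert 0.0 <= s1 <= 1.0

    def test_pairwise_matrix_consistent_with_scalar(self, diamond_dag):
        terms = ["A", "X", "Y", "R"]
        mat = pairwise_similarity(terms, diamond_dag)
        for a in terms:
            for b in terms:
                assert mat.loc[a, b] == pytest.approx(
                    wang_similarity(a, b, diamond_dag), rel=1e-12
                )

    def test_ontology_round_trip(self, diamond_dag, tmp_path):
        write_ontology(diamond_dag, tmp_path / "dag.tsv")
        back = read_ontology(tmp_path / "dag.tsv")
        assert {t: set(p) for t, p in back.parents.items()} == {
            t: set(p) for t, p in diamond_dag.parents.items()
        }

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            _dag({"A": (("B", "is_a"),), "B": (("A", "is_a"),)})


class TestClustering:
    def test_single_term_single_group(self):
        assert cluster_terms(["T1"], np.ones((1, 1))) == [["T1"]]

    def test_fewer_terms_than_groups_gives_singletons(self):
        terms = [f"T{i}" for i in range(7)]
        groups = cluster_terms(terms, np.eye(7), n_groups=10)
        assert sorted(map(tuple, groups)) == sorted((t,) for t in terms)

    def test_two_separated_blocks_recovered(self):
        terms = [f"T{i}" for i in range(6)]
        sim = np.full((6, 6), 0.05)
        sim[:3, :3] = 0.9
        sim[3:, 3:] = 0.9
        np.fill_diagonal(sim, 1.0)
        groups = cluster_terms(terms, sim, n_groups=2)
        assert {frozenset(g) for g in groups} == {
            frozenset({"T0", "T1", "T2"}),
            frozenset({"T3", "T4", "T5"}),
        }

    def test_groups_partition_input(self, rng):
        terms = [f"T{i}" for i in range(12)]
        raw = rng.random((12, 12))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        groups = cluster_terms(terms, sim, n_groups=4)
        assert len(groups) == 4
        flat = [t for g in groups for t in g]
        assert sorted(flat) == sorted(terms)

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError):
            cluster_terms(["A", "B"], bad, n_groups=2)


def _enrichment_frame(rows):
    return pd.DataFrame(
        rows, columns=["term_id", "p", "p_adjusted", "significant"]
    ).assign(name=lambda d: d["term_id"])


class TestRepresentative:
    def test_singleton_group(self):
        enr = _enrichment_frame([("T1", 0.01, 0.02, True)])
        assert select_representative(["T1"], enr) == "T1"

    def test_lowest_adjusted_p_wins(self):
        enr = _enrichment_frame([("T1", 0.005, 0.01, True), ("T2", 0.0005, 0.001, True)])
        assert select_representative(["T1", "T2"], enr) == "T2"

    def test_tie_broken_by_raw_p_then_id(self):
        enr = _enrichment_frame(
            [("T2", 0.004, 0.01, True), ("T1", 0.005, 0.01, True)]
        )
        assert select_representative(["T1", "T2"], enr) == "T2"
        enr = _enrichment_frame(
            [("Tb", 0.005, 0.01, True), ("Ta", 0.005, 0.01, True)]
        )
        assert select_representative(["Ta", "Tb"], enr) == "Ta"

    def test_member_without_result_raises(self):
        enr = _enrichment_frame([("T1", 0.01, 0.02, True)])
        with pytest.raises(KeyError):
            select_representative(["T1", "T9"], enr)


class TestAggregation:
    def test_groups_cover_significant_terms_and_are_numbered_by_p(self, sibling_dag):
        enr = pd.DataFrame(
            {
                "term_id": ["A", "B", "R"],
                "name": ["a", "b", "root"],
                "p": [0.0001, 0.01, 0.5],
                "p_adjusted": [0.0003, 0.03, 0.5],
                "significant": [True, True, False],
            }
        )
        groups = aggregate_function_groups(enr, sibling_dag, n_groups=10)
        members = sorted(t for g in groups for t in g.members)
        assert members == ["A", "B"]  # only significant terms are grouped
        assert groups[0].group_id == 1
        assert groups[0].representative == "A"  # lowest adjusted p first

    def test_no_significant_terms_gives_no_groups(self, sibling_dag):
        enr = pd.DataFrame(
            {
                "term_id": ["A"], "name": ["a"], "p": [0.9],
                "p_adjusted": [0.9], "significant": [False],
            }
        )
        assert aggregate_function_groups(enr, sibling_dag) == []

    def test_representative_must_be_member(self):
        with pytest.raises(ValueError):
            FunctionGroup(
                group_id=1, members=("T1",), representative="T2",
                representative_p_adjusted=0.01,
            )
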