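import networkx as nx
import numpy as np
import pandas as pd
import pytest

from subdyquency import (
    CohortError,
    FrequencyVectors,
    MutationMatrix,
    OutlierMatrix,
    PatientBipartite,
    SubdyquencyError,
    WalkConfig,
    WalkScores,
    aggregate_and_rank,
    build_catalog,
    build_patient_bipartite,
    run_subdyquency,
    walk_patient,
    weight_bipartite,
)
from subdyquency.simulate import CohortConfig, generate_cohort


def _binary(values, patients, genes, cls):
    return cls(pd.DataFrame(np.asarray(values), index=patients, columns=genes))


class TestBuildBipartite:
    def _fixture(self):
        graph = nx.Graph([("g1", "o1"), ("g2", "o2")])
        mut = _binary([[1, 1, 1]], ["p1"], ["g1", "g2", "g3"], MutationMatrix)
        out = _binary([[1]], ["p1"], ["o1"], OutlierMatrix)
        return graph, mut, out

    def test_connection_rule_drops_unlinked_nodes(self):
        graph, mut, out = self._fixture()
        b = build_patient_bipartite("p1", mut, out, graph)
        assert b.mutated_nodes == ["g1"]
        assert b.outlying_nodes == ["o1"]
        assert b.W.tolist() == [[1.0]]

    def test_patient_without_mutations_is_empty(self):
        graph = nx.Graph([("g1", "o1")])
        mut = _binary([[1], [0]], ["p1", "p2"], ["g1"], MutationMatrix)
        out = _binary([[1], [1]], ["p1", "p2"], ["o1"], OutlierMatrix)
        b = build_patient_bipartite("p2", mut, out, graph)
        assert b.is_empty

    def test_gene_on_both_sides(self):
        # 'x' is both mutated and outlying; it pairs with neighbors, never itself
        graph = nx.Graph([("x", "y")])
        mut = _binary([[1, 1]], ["p1"], ["x", "y"], MutationMatrix)
        out = _binary([[1, 1]], ["p1"], ["x", "y"], OutlierMatrix)
        b = build_patient_bipartite("p1", mut, out, graph)
        assert set(b.mutated_nodes) == {"x", "y"}
        assert set(b.outlying_nodes) == {"x", "y"}
        i, j = b.mutated_nodes.index("x"), b.outlying_nodes.index("x")
        assert b.W[i, j] == 0.0

    def test_unknown_patient_rejected(self):
        graph, mut, out = self._fixture()
        with pytest.raises(CohortError, match="p9"):
            build_patient_bipartite("p9", mut, out, graph)


class TestWeightBipartite:
    def test_weights_follow_localization(self, human_catalog):
        b = PatientBipartite("p", ["a"], ["b", "c"], np.array([[1.0, 1.0]]))
        loc = {"a": {"Nucleus"}, "b": {"Nucleus"}, "c": {"Cytosol"}}
        wb = weight_bipartite(b, human_catalog, loc)
        assert wb.W[0, 0] == 1.0  # shared largest compartment
        assert wb.W[0, 1] == pytest.approx(825 / 13938)  # disjoint -> floor

    def test_absent_edges_stay_zero(self, human_catalog):
        b = PatientBipartite("p", ["a"], ["b", "c"], np.array([[1.0, 0.0]]))
        wb = weight_bipartite(b, human_catalog, {"a": {"Nucleus"}, "b": {"Nucleus"}})
        assert wb.W[0, 1] == 0.0

    def test_empty_graph_unchanged(self, human_catalog):
        b = PatientBipartite("p", [], [], np.zeros((0, 0)))
        assert weight_bipartite(b, human_catalog, {}).is_empty


def _freq(m, o, n=10):
    return FrequencyVectors(n=n, mutated=m, outlying=o)


class TestWalkPatient:
    def test_hand_example(self):
        b = PatientBipartite("p", ["m"], ["o"], np.array([[0.5]]))
        scores = walk_patient(b, _freq({"m": 0.4}, {"o": 0.2}), WalkConfig(alpha=0.5))
        # pass 1: 0.5*0.4 + 0.5*0.5*0.2        = 0.25
        # pass 2: 0.5*0.2 + 0.5*0.5*0.25       = 0.1625
        # pass 3: 0.5*0.4 + 0.5*0.5*0.1625     = 0.240625
        assert scores.ro["o"] == pytest.approx(0.1625, abs=1e-12)
        assert scores.rm["m"] == pytest.approx(0.240625, abs=1e-12)

    def test_alpha_one_returns_own_frequency(self):
        rng = np.random.default_rng(0)
        b = PatientBipartite(
            "p", ["m1", "m2"], ["o1", "o2", "o3"], rng.random((2, 3))
        )
        m = {"m1": 0.3, "m2": 0.7}
        scores = walk_patient(b, _freq(m, {"o1": 0.1, "o2": 0.2, "o3": 0.3}), WalkConfig(alpha=1.0))
        assert scores.rm == pytest.approx(m)

    def test_all_ones_fixed_point(self):
        b = PatientBipartite("p", ["m"], ["o"], np.array([[1.0]]))
        scores = walk_patient(b, _freq({"m": 1.0}, {"o": 1.0}), WalkConfig(alpha=0.5))
        assert scores.rm["m"] == pytest.approx(1.0)

    def test_missing_frequency_rejected(self):
        b = PatientBipartite("p", ["m"], ["o"], np.array([[1.0]]))
        with pytest.raises(SubdyquencyError, match="frequency"):
            walk_patient(b, _freq({"m": 0.5}, {}))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_weights_and_frequencies(self, seed):
        """All walk operations are nonnegative-linear: growing any edge weight
        or frequency never lowers a mutated gene's score."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6, size=2)
        W = rng.random((n, m)) * rng.integers(0, 2, size=(n, m))
        mut_nodes = [f"m{i}" for i in range(n)]
        out_nodes = [f"o{j}" for j in range(m)]
        M = {g: rng.uniform(0.05, 1) for g in mut_nodes}
        O = {g: rng.uniform(0.05, 1) for g in out_nodes}
        base = walk_patient(
            PatientBipartite("p", mut_nodes, out_nodes, W), _freq(M, O)
        )
        W2 = W.copy()
        W2[rng.integers(n), rng.integers(m)] += 0.5
        bigger_w = walk_patient(
            PatientBipartite("p", mut_nodes, out_nodes, W2), _freq(M, O)
        )
        O2 = dict(O)
        O2[out_nodes[0]] += 0.5
        bigger_o = walk_patient(
            PatientBipartite("p", mut_nodes, out_nodes, W), _freq(M, O2)
        )
        for g in mut_nodes:
            assert base.rm[g] >= 0
            assert bigger_w.rm[g] >= base.rm[g] - 1e-15
            assert bigger_o.rm[g] >= base.rm[g] - 1e-15


class TestAggregateAndRank:
    def test_scores_sum_across_patients(self):
        freq = _freq({"a": 0.5, "b": 0.5}, {})
        scores = [
            WalkScores("p1", {"a": 0.3}, {}),
            WalkScores("p2", {"a": 0.5, "b": 0.1}, {}),
        ]
        ranking = aggregate_and_rank(scores, freq)
        assert ranking.genes == ["a", "b"]
        assert ranking.table.loc[0, "score"] == pytest.approx(0.8)

    def test_tie_break_frequency_then_symbol(self):
        freq = _freq({"a": 0.2, "b": 0.4, "c": 0.4}, {})
        scores = [WalkScores("p1", {"a": 0.5, "b": 0.5, "c": 0.5}, {})]
        ranking = aggregate_and_rank(scores, freq)
        assert ranking.genes == ["b", "c", "a"]

    def test_empty_input_rejected(self):
        with pytest.raises(CohortError):
            aggregate_and_rank([], _freq({}, {}))

    def test_benchmark_flags(self):
        freq = _freq({"a": 0.5, "b": 0.5}, {})
        ranking = aggregate_and_rank(
            [WalkScores("p1", {"a": 1.0, "b": 0.5}, {})], freq, benchmark={"b"}
        )
        assert ranking.table["is_benchmark"].tolist() == [False, True]


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(
        CohortConfig(n_patients=30, n_genes=50, n_drivers=5, driver_extra_degree=5, seed=3)
    )


class TestRunPipeline:
    def test_deterministic(self, cohort):
        args = (cohort.mutation, cohort.expression, cohort.graph, cohort.localization)
        assert run_subdyquency(*args) == run_subdyquency(*args)

    def test_patient_order_invariance(self, cohort):
        order = list(reversed(cohort.mutation.patients))
        r1 = run_subdyquency(
            cohort.mutation, cohort.expression, cohort.graph, cohort.localization
        )
        r2 = run_subdyquency(
            cohort.mutation.subset_patients(order),
            cohort.expression.subset_patients(order),
            cohort.graph,
            cohort.localization,
        )
        # summation order differs, so allow floating round-off
        assert r1.genes == r2.genes
        assert r1.table["score"].to_numpy() == pytest.approx(
            r2.table["score"].to_numpy(), rel=1e-12
        )

    def test_empty_cohort_intersection_rejected(self, cohort):
        other = cohort.expression.data.copy()
        other.index = [f"q{i}" for i in range(len(other))]
        from subdyquency import ExpressionMatrix

        with pytest.raises(CohortError):
            run_subdyquency(
                cohort.mutation,
                ExpressionMatrix(other),
                cohort.graph,
                cohort.localization,
            )
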