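"""GO co-annotation networks, intersect scoring, permutation nulls."""

import numpy as np
import pandas as pd
import pytest

import penirf as pf
from penirf.exceptions import DegenerateNullError, ParameterError


def _ann(records):
    return pd.DataFrame(records, columns=["gene_id", "term_id"])


class TestBuildGONetwork:
    def test_triplet_term_gives_half_weights(self):
        net = pf.build_go_network(_ann([("A", "T1"), ("B", "T1"), ("C", "T1")]))
        assert net.weights == {
            ("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5
        }

    def test_multiply_shared_pair_keeps_max_weight(self):
        records = [("A", "small"), ("B", "small"), ("C", "small")]
        records += [(g, "big") for g in "ABCDEFGHIJK"]  # 11 genes -> 0.1
        net = pf.build_go_network(_ann(records))
        assert net.weights[("A", "B")] == pytest.approx(0.5)
        assert net.weights[("D", "E")] == pytest.approx(0.1)

    def test_term_at_size_cutoff_contributes_nothing(self):
        records = [(f"g{i}", "huge") for i in range(1000)]
        assert pf.build_go_network(_ann(records)).n_edges == 0
        records = [(f"g{i}", "ok") for i in range(999)]
        net = pf.build_go_network(_ann(records))
        assert net.n_edges == 999 * 998 // 2
        assert next(iter(net.weights.values())) == pytest.approx(1 / 998)

    def test_singleton_terms_and_duplicates_ignored(self):
        net = pf.build_go_network(
            _ann([("A", "T1"), ("A", "T1"), ("B", "T2"), ("A", "T2")])
        )
        assert net.weights == {("A", "B"): 1.0}


class TestIntersectScore:
    def test_disjoint_networks_score_zero(self):
        go = pf.build_go_network(_ann([("A", "T"), ("B", "T")]))
        pen = pd.DataFrame({"source": ["X"], "target": ["Y"], "weight": [1.0]})
        assert pf.intersect_score(pen, go) == 0.0

    def test_figure_style_toy_sums_shared_pair_weights(self):
        # two of three predicted connections have GO support: 0.05 + 0.0214
        go = pf.GONetwork(
            weights={("D", "E"): 0.05, ("E", "F"): 0.0214},
            nodes=frozenset("DEF"),
        )
        pen = pd.DataFrame(
            {"source": ["D", "F", "A"], "target": ["E", "E", "B"],
             "weight": [0.9, 0.8, 0.7]}
        )
        assert pf.intersect_score(pen, go) == pytest.approx(0.0714)

    def test_both_directions_count_once(self):
        go = pf.GONetwork(weights={("A", "B"): 0.4}, nodes=frozenset("AB"))
        pen = pd.DataFrame(
            {"source": ["A", "B"], "target": ["B", "A"], "weight": [1.0, 1.0]}
        )
        assert pf.intersect_score(pen, go) == pytest.approx(0.4)

    def test_score_bounded_by_total_go_weight(self, rng):
        genes = [f"g{i}" for i in range(12)]
        ann = pf.generate_go_annotations(genes, [4, 4, 4], seed=1)
        go = pf.build_go_network(ann)
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        pen = pd.DataFrame(pairs, columns=["source", "target"])
        pen["weight"] = 1.0
        score = pf.intersect_score(pen, go)
        assert 0.0 <= score <= go.total_weight + 1e-12
        assert score == pytest.approx(go.total_weight)  # complete PEN hits all


class TestNullDistribution:
    @pytest.fixture
    def small_pen_and_go(self):
        genes = [f"g{i}" for i in range(10)]
        go = pf.build_go_network(pf.generate_go_annotations(genes, [3, 4], seed=0))
        pen = pd.DataFrame(
            {"source": genes[:5], "target": genes[5:], "weight": np.ones(5)}
        )
        return pen, go

    def test_scores_nonnegative_and_reproducible(self, small_pen_and_go):
        pen, go = small_pen_and_go
        a = pf.null_distribution(pen, go, n_permutations=50, seed=4)
        b = pf.null_distribution(pen, go, n_permutations=50, seed=4)
        assert np.array_equal(a, b)
        assert (a >= 0).all()

    def test_complete_graph_is_invariant_under_relabeling(self):
        genes = list("ABCDE")
        go = pf.build_go_network(_ann([(g, "T") for g in "ABC"]))
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        pen = pd.DataFrame(pairs, columns=["source", "target"])
        pen["weight"] = 1.0
        observed = pf.intersect_score(pen, go)
        null = pf.null_distribution(pen, go, n_permutations=30, seed=0)
        assert np.allclose(null, observed)

    def test_joint_relabeling_leaves_score_unchanged(self, small_pen_and_go, rng):
        pen, go = small_pen_and_go
        genes = sorted(set(pen.source) | set(pen.target) | set(go.nodes))
        mapping = dict(zip(genes, rng.permutation(genes)))
        pen2 = pen.assign(
            source=pen.source.map(mapping), target=pen.target.map(mapping)
        )
        go2 = pf.GONetwork(
            weights={
                tuple(sorted((mapping[a], mapping[b]))): w
                for (a, b), w in go.weights.items()
            },
            nodes=frozenset(mapping[g] for g in go.nodes),
        )
        assert pf.intersect_score(pen2, go2) == pytest.approx(
            pf.intersect_score(pen, go)
        )

    def test_bad_permutation_count_rejected(self, small_pen_and_go):
        pen, go = small_pen_and_go
        with pytest.raises(ParameterError):
            pf.null_distribution(pen, go, n_permutations=0)


class TestTStatistic:
    def test_observed_at_null_mean_gives_zero(self):
        assert pf.t_statistic(5.0, [4.0, 5.0, 6.0]) == pytest.approx(0.0)

    def test_matches_moment_formula(self, rng):
        null = rng.normal(10, 2, size=500)
        t = pf.t_statistic(25.0, null)
        assert t == pytest.approx(
            pf.t_statistic_from_moments(
                25.0, null.mean(), null.std(ddof=1)
            )
        )

    def test_zero_spread_null_rejected(self):
        with pytest.raises(DegenerateNullError):
            pf.t_statistic(1.0, [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateNullError):
            pf.t_statistic_from_moments(1.0, 0.5, 0.0)

    def test_null_qq_is_near_diagonal_for_normal_scores(self, rng):
        from penirf.go import null_qq

        theo, z = null_qq(rng.normal(3.0, 1.5, 1000))
        assert theo.shape == z.shape == (1000,)
        # Gaussian null: standardized order statistics track normal quantiles
        assert np.max(np.abs(theo - z)) < 0.5


class TestCoexpression:
    def test_perfect_proportionality_ranks_first(self, rng):
        X = rng.standard_normal((50, 4))
        X[:, 1] = 2.0 * X[:, 0]
        frame = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        edges = pf.coexpression_network(frame, 1.0)
        assert (edges.iloc[0].gene_a, edges.iloc[0].gene_b) == ("a", "b")
        assert edges.iloc[0].weight == pytest.approx(1.0)

    def test_all_pairs_evaluated(self, rng):
        frame = pd.DataFrame(rng.standard_normal((30, 6)))
        edges = pf.coexpression_network(frame, 1.0)
        assert len(edges) == 15  # 6*5/2, continuous data has no zero |r|

    def test_negative_correlation_counts_via_absolute_value(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 2] = -X[:, 0]
        edges = pf.coexpression_network(pd.DataFrame(X, columns=list("abc")), 0.4)
        top = edges.iloc[0]
        assert {top.gene_a, top.gene_b} == {"a", "c"}
        assert top.weight == pytest.approx(1.0)

    def test_constant_gene_excluded_with_warning(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            edges = pf.coexpression_network(pd.DataFrame(X, columns=list("abc")), 1.0)
        assert not {"b"} & (set(edges.gene_a) | set(edges.gene_b))
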