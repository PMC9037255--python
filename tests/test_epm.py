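import numpy as np
import pytest

from epmkit.data_io import ExpressionMatrix
from epmkit.epm import (
    benchmark_vector,
    compute_epm,
    delta_rank,
    edge_perturbation,
    feature_transform,
    rank_transform,
)
from epmkit.network import build_network


def _expr(values, genes=None, cohort=None):
    values = np.asarray(values, float)
    genes = genes or [chr(65 + i) for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, cohort or ["tumor"] * values.shape[1])


class TestRankTransform:
    def test_ascending_ranks(self):
        m = _expr([[5, 5], [1, 1], [3, 3]])  # A=5, B=1, C=3
        r = rank_transform(m)
        np.testing.assert_array_equal(r.ranks[:, 0], [3, 1, 2])

    def test_tie_average(self):
        m = _expr([[2, 0], [2, 0], [1, 1]])
        r = rank_transform(m)
        np.testing.assert_array_equal(r.ranks[:, 0], [2.5, 2.5, 1])

    def test_all_equal_sample(self):
        m = _expr([[1, 9], [1, 9], [1, 9], [1, 9]])
        np.testing.assert_array_equal(rank_transform(m).ranks[:, 0], [2.5] * 4)

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(3)
        m = _expr(rng.integers(0, 5, size=(7, 4)))  # plenty of ties
        r = rank_transform(m)
        np.testing.assert_allclose(r.ranks.sum(axis=0), 7 * 8 / 2)


class TestDeltaRank:
    def test_sign_convention(self):
        # ranks: A=3, B=1, C=2; canonical (A,B): delta = 3 - 1 = 2
        m = _expr([[5, 5], [1, 1], [3, 3]])
        net = build_network([("A", "B"), ("A", "C")])
        d = delta_rank(rank_transform(m), net)
        assert d.edges == [("A", "B"), ("A", "C")]
        np.testing.assert_array_equal(d.delta[:, 0], [2, 1])

    def test_equal_ranks_give_zero(self):
        m = _expr([[2, 1], [2, 1], [1, 5]])
        d = delta_rank(rank_transform(m), build_network([("A", "B")]))
        assert d.delta[0, 0] == 0

    def test_missing_gene_error(self):
        m = _expr([[1, 2], [3, 4]], genes=["A", "B"])
        with pytest.raises(KeyError, match="Z"):
            delta_rank(rank_transform(m), build_network([("A", "Z")]))


class TestBenchmark:
    def test_rank_of_mean(self):
        normal = _expr([[4, 4], [2, 2], [3, 3]], cohort=["normal"] * 2)
        net = build_network([("A", "B")])
        b = benchmark_vector(normal, net)
        assert b.delta_bar[0] == 2  # ranks A=3, B=1

    def test_single_normal_sample_equals_its_delta(self):
        normal = ExpressionMatrix(
            ["A", "B", "C"], ["n1", "n2"], np.array([[4.0, 4], [2, 2], [3, 3]]),
            ["normal", "normal"],
        )
        # two identical normal columns: the mean profile is the sample itself
        net = build_network([("A", "C"), ("B", "C")])
        b = benchmark_vector(normal, net)
        d = delta_rank(rank_transform(normal), net)
        np.testing.assert_array_equal(b.delta_bar, d.delta[:, 0])

    def test_constant_mean_profile_gives_zero(self):
        normal = _expr([[1, 1], [1, 1], [1, 1]], cohort=["normal"] * 2)
        b = benchmark_vector(normal, build_network([("A", "B"), ("B", "C")]))
        np.testing.assert_array_equal(b.delta_bar, [0, 0])

    def test_mean_of_delta_variant(self):
        normal = _expr([[1, 9], [5, 5], [9, 1]], cohort=["normal"] * 2)
        net = build_network([("A", "C")])
        b = benchmark_vector(normal, net, method="mean_of_delta")
        # per-sample deltas are -2 and +2; their mean is 0
        assert b.delta_bar[0] == 0


class TestEdgePerturbation:
    def test_subtraction(self):
        m = _expr([[5, 1], [1, 3], [3, 5]])
        net = build_network([("A", "B")])
        d = delta_rank(rank_transform(m), net)
        normal = _expr([[4, 4], [2, 2], [3, 3]], cohort=["normal"] * 2)
        b = benchmark_vector(normal, net)
        e = edge_perturbation(d, b)
        np.testing.assert_array_equal(e.perturbation[0], d.delta[0] - 2)

    def test_edge_mismatch_error(self):
        m = _expr([[5, 1], [1, 3], [3, 5]])
        d = delta_rank(rank_transform(m), build_network([("A", "B")]))
        normal = _expr([[4, 4], [2, 2], [3, 3]], cohort=["normal"] * 2)
        b = benchmark_vector(normal, build_network([("A", "C")]))
        with pytest.raises(ValueError):
            edge_perturbation(d, b)

    def test_sample_equal_to_normal_mean_has_zero_row(self):
        rng = np.random.default_rng(0)
        normal_vals = rng.uniform(1, 100, size=(20, 5))
        mean = normal_vals.mean(axis=1)
        genes = [f"g{i:02d}" for i in range(20)]
        combined = ExpressionMatrix(
            genes,
            [f"n{j}" for j in range(5)] + ["t0"],
            np.column_stack([normal_vals, mean]),
            ["normal"] * 5 + ["tumor"],
        )
        net = build_network([(genes[i], genes[i + 1]) for i in range(19)])
        e = compute_epm(combined, net)
        np.testing.assert_array_equal(e.perturbation[:, 5], 0.0)


class TestFeatureTransform:
    @pytest.mark.parametrize("delta,expected", [(0, 0.0), (7, 3.0), (-3, -2.0)])
    def test_signed_log(self, delta, expected):
        m = _expr([[5, 1], [1, 3], [3, 5]])
        net = build_network([("A", "B")])
        e = edge_perturbation(
            delta_rank(rank_transform(m), net),
            benchmark_vector(_expr([[4, 4], [2, 2], [3, 3]], cohort=["normal"] * 2), net),
        )
        e.perturbation = np.array([[float(delta)]])
        e.sample_ids = ["s0"]
        e.cohort = ["tumor"]
        f = feature_transform(e)
        assert f.features[0, 0] == pytest.approx(expected)

    def test_abs_log_mode(self):
        m = _expr([[5, 1], [1, 3], [3, 5]])
        net = build_network([("A", "B")])
        e = edge_perturbation(
            delta_rank(rank_transform(m), net),
            benchmark_vector(_expr([[4, 4], [2, 2], [3, 3]], cohort=["normal"] * 2), net),
        )
        e.perturbation = np.array([[-7.0]])
        e.sample_ids = ["s0"]
        e.cohort = ["tumor"]
        assert feature_transform(e, mode="abs_log").features[0, 0] == pytest.approx(3.0)


class TestInvariants:
    def _setup(self, seed=1, g=30, s=6):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 50, size=(g, s))
        genes = [f"g{i:02d}" for i in range(g)]
        m = ExpressionMatrix(
            genes,
            [f"x{j}" for j in range(s)],
            vals,
            ["normal"] * 2 + ["tumor"] * (s - 2),
        )
        pairs = [(genes[i], genes[(i * 7 + 3) % g]) for i in range(g) if genes[i] != genes[(i * 7 + 3) % g]]
        return m, build_network(pairs)

    def test_monotone_invariance(self):
        m, net = self._setup()
        base = compute_epm(m, net)
        vals = m.values.copy()
        vals[:, 3] = np.exp(vals[:, 3] / 10.0)  # strictly increasing transform
        m2 = ExpressionMatrix(m.gene_ids, m.sample_ids, vals, m.cohort)
        after = compute_epm(m2, net)
        np.testing.assert_array_equal(base.perturbation[:, 3], after.perturbation[:, 3])

    def test_antisymmetry_under_edge_flip(self):
        m, _ = self._setup()
        ranks = rank_transform(m)
        net_ab = build_network([("g00", "g05")])
        d = delta_rank(ranks, net_ab)
        i = m.gene_ids.index("g00")
        j = m.gene_ids.index("g05")
        flipped = ranks.ranks[j, :] - ranks.ranks[i, :]
        np.testing.assert_array_equal(d.delta[0], -flipped)

    def test_perturbation_bound(self):
        m, net = self._setup(seed=5)
        e = compute_epm(m, net)
        g = m.n_genes
        assert np.all(np.abs(e.perturbation) <= 2 * (g - 1))
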