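import math

import numpy as np
import pytest
from scipy import stats

from grngpea.errors import ConfigError, DataError
from grngpea.inference import (
    bc3net,
    bootstrap_indices,
    c3net,
    mi_matrix,
    mi_pearson,
    null_mi_pool,
    relevance_network,
)
from grngpea.io_formats import ExpressionMatrix


def _matrix(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


class TestMiPearson:
    def test_zero_correlation_gives_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal after centering
        assert mi_pearson(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_half_correlation_analytic(self, rng):
        # construct an exact rho=0.5 pair
        x = rng.standard_normal(500)
        z = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        z = (z - z.mean()) / z.std()
        z = z - (z @ x) / (x @ x) * x  # orthogonalize
        z = (z - z.mean()) / z.std()
        y = 0.5 * x + math.sqrt(1 - 0.25) * z
        assert mi_pearson(x, y) == pytest.approx(-0.5 * math.log(0.75), abs=1e-9)

    def test_perfect_correlation_is_capped_finite(self, rng):
        x = rng.standard_normal(50)
        val = mi_pearson(x, x)
        assert math.isfinite(val)
        assert val == pytest.approx(-0.5 * math.log(1e-12), rel=1e-6)

    def test_errors(self, rng):
        with pytest.raises(DataError):
            mi_pearson(np.ones(10), rng.standard_normal(10))
        with pytest.raises(DataError):
            mi_pearson(np.arange(2.0), np.arange(2.0))


class TestMiMatrix:
    def test_matches_pairwise_oracle(self, rng):
        m = _matrix(rng.standard_normal((4, 50)))
        mim = mi_matrix(m)
        for i in range(4):
            assert mim.values[i, i] == 0.0
            for j in range(i + 1, 4):
                expected = mi_pearson(m.values[i], m.values[j])
                assert mim.values[i, j] == pytest.approx(expected, rel=1e-12)
                assert mim.values[j, i] == mim.values[i, j]

    def test_duplicated_genes_hit_the_cap(self, rng):
        row = rng.standard_normal(30)
        m = _matrix(np.vstack([row, row]))
        mim = mi_matrix(m)
        assert mim.values[0, 1] == pytest.approx(-0.5 * math.log(1e-12), rel=1e-6)

    def test_constant_gene_is_error(self, rng):
        m = _matrix(np.vstack([np.ones(30), rng.standard_normal(30)]))
        with pytest.raises(DataError):
            mi_matrix(m)


class TestNullPool:
    def test_deterministic_under_seed(self, small_matrix):
        a = null_mi_pool(small_matrix, n_draws=2000, seed=4)
        b = null_mi_pool(small_matrix, n_draws=2000, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empirical_p_of_own_maximum(self, small_matrix):
        pool = null_mi_pool(small_matrix, n_draws=5000, seed=5)
        p = pool.empirical_pvalue(pool.values[-1])
        assert p == pytest.approx(2 / 5001)  # the max itself ties once

    def test_null_distribution_matches_independence(self, rng):
        """Permutation null == analytic null for Gaussian data.

        Under independence rho^2 ~ Beta(1/2, (n-2)/2); the pool's MI
        values, transformed back to rho^2, should be uniform under that
        CDF (KS check on strongly dependent input data).
        """
        n = 60
        x = rng.standard_normal((1, n))
        data = np.vstack([x + 0.05 * rng.standard_normal((1, n)) for _ in range(6)])
        pool = null_mi_pool(_matrix(data), n_draws=3000, seed=6)
        rho_sq = -np.expm1(-2.0 * pool.values)
        u = stats.beta.cdf(rho_sq, 0.5, (n - 2) / 2)
        ks = stats.kstest(u, "uniform")
        assert ks.pvalue > 0.001


def _c3net_bruteforce(m, pool, alpha):
    """Straight-line reference: full MI matrix, per-gene argmax, same test."""
    p, _ = m.values.shape
    mi = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                mi[i, j] = mi_pearson(m.values[i], m.values[j])
    ids = m.gene_ids  # fixtures use sorted ids, so argmax order = id order
    assert ids == sorted(ids)
    edges = {}
    for i in range(p):
        row = [mi[i, j] if j != i else -np.inf for j in range(p)]
        j = int(np.argmax(row))
        e = tuple(sorted((ids[i], ids[j])))
        edges[e] = max(edges.get(e, -np.inf), row[j])
    kept = set()
    for e, val in edges.items():
        n_ge = int(np.sum(pool.values >= val))
        p_emp = (1 + n_ge) / (pool.n_draws + 1)
        if min(1.0, p_emp * p) <= alpha:
            kept.add(e)
    return kept


class TestC3Net:
    def test_matches_bruteforce_oracle(self, rng):
        data = rng.standard_normal((6, 40))
        data[1] = data[0] + 0.1 * rng.standard_normal(40)
        data[3] = -data[2] + 0.2 * rng.standard_normal(40)
        m = _matrix(data)
        pool = null_mi_pool(m, n_draws=5000, seed=7)
        net = c3net(m, alpha=0.05, pool=pool)
        assert set(net.edge_set()) == _c3net_bruteforce(m, pool, 0.05)

    def test_duplicated_pair_is_found(self, rng):
        data = rng.standard_normal((8, 50))
        data[5] = data[2]  # exact duplicates
        m = _matrix(data)
        pool = null_mi_pool(m, n_draws=5000, seed=8)
        net = c3net(m, alpha=0.05, pool=pool)
        assert ("g2", "g5") in net.edge_set()

    def test_alpha_to_zero_empties_the_network(self, rng):
        m = _matrix(rng.standard_normal((6, 40)))
        pool = null_mi_pool(m, n_draws=2000, seed=9)
        net = c3net(m, alpha=1e-12, pool=pool)
        assert net.n_edges == 0

    def test_edge_count_bounded_by_gene_count(self, rng):
        m = _matrix(rng.standard_normal((20, 60)))
        pool = null_mi_pool(m, n_draws=2000, seed=10)
        net = c3net(m, alpha=1.0, pool=pool)
        assert 0 < net.n_edges <= 20


class TestBC3Net:
    def test_reduces_to_c3net_without_resampling(self, rng):
        m = _matrix(rng.standard_normal((10, 50)))
        pool = null_mi_pool(m, n_draws=5000, seed=11)
        single = c3net(m, alpha=0.05, pool=pool)
        bagged = bc3net(m, B=1, alpha_edge=1.0, alpha_c3=0.05,
                        pool=pool, resample=False)
        assert bagged.edge_set() == single.edge_set()
        assert all(d.weight == 1.0 for d in bagged.edges().values())

    def test_retained_edges_subset_of_ensemble_union(self, rng):
        m = _matrix(rng.standard_normal((12, 40)))
        pool = null_mi_pool(m, n_draws=3000, seed=12)
        seed, B = 13, 10
        union = set()
        for b in range(B):
            idx = bootstrap_indices(seed, b, m.n_samples)
            boot = ExpressionMatrix(m.gene_ids, [f"r{i}" for i in range(m.n_samples)],
                                    m.values[:, idx])
            union |= set(c3net(boot, alpha=0.05, pool=pool).edge_set())
        net = bc3net(m, B=B, seed=seed, pool=pool)
        assert set(net.edge_set()) <= union

    def test_alpha_monotonicity(self, rng):
        m = _matrix(rng.standard_normal((10, 40)))
        pool = null_mi_pool(m, n_draws=3000, seed=14)
        loose = bc3net(m, B=10, alpha_edge=0.5, seed=14, pool=pool)
        strict = bc3net(m, B=10, alpha_edge=0.01, seed=14, pool=pool)
        assert strict.edge_set() <= loose.edge_set()

    def test_ecr_are_multiples_of_one_over_B(self, rng):
        m = _matrix(rng.standard_normal((10, 40)))
        pool = null_mi_pool(m, n_draws=3000, seed=15)
        B = 8
        net = bc3net(m, B=B, alpha_edge=1.0, seed=15, pool=pool)
        for data in net.edges().values():
            count = data.weight * B
            assert count == pytest.approx(round(count))
            assert 1 <= round(count) <= B

    def test_deterministic_under_seed(self, rng):
        m = _matrix(rng.standard_normal((10, 40)))
        a = bc3net(m, B=5, seed=16, n_null=2000)
        b = bc3net(m, B=5, seed=16, n_null=2000)
        assert a.edge_set() == b.edge_set()
        assert [d.weight for d in a.edges().values()] == \
               [d.weight for d in b.edges().values()]

    def test_invalid_B(self, small_matrix):
        with pytest.raises(ConfigError):
            bc3net(small_matrix, B=0)


class TestRelevanceNetwork:
    def test_abscorr_keeps_exact_topk_count(self, rng):
        m = _matrix(rng.standard_normal((10, 60)))
        net = relevance_network(m, method="abscorr", percentile=0.9)
        assert net.n_edges == math.ceil(0.1 * 45)

    def test_topk_edges_are_the_sorted_top(self, rng):
        m = _matrix(rng.standard_normal((10, 60)))
        rho = np.corrcoef(m.values)
        iu, ju = np.triu_indices(10, k=1)
        scores = sorted(np.abs(rho[iu, ju]), reverse=True)
        k = math.ceil(0.1 * 45)
        net = relevance_network(m, method="abscorr", percentile=0.9)
        kept = sorted((d.weight for d in net.edges().values()), reverse=True)
        np.testing.assert_allclose(kept, scores[:k])

    def test_extreme_percentile_keeps_single_top_pair(self, rng):
        m = _matrix(rng.standard_normal((10, 60)))
        net = relevance_network(m, method="abscorr", percentile=0.999)
        assert net.n_edges == 1  # ceil(0.001 * 45)

    def test_clr_zero_score_pairs_never_selected(self, rng):
        m = _matrix(rng.standard_normal((10, 60)))
        net = relevance_network(m, method="clr", percentile=0.5)
        assert all(d.weight > 0 for d in net.edges().values())

    def test_parameter_validation(self, rng):
        m = _matrix(rng.standard_normal((5, 30)))
        with pytest.raises(ConfigError):
            relevance_network(m, percentile=1.5)
        with pytest.raises(ConfigError):
            relevance_network(m, method="wgcna-soft", percentile=0.5)
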