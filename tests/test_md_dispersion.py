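"""Multivariate dispersion test: oracles, identities and invariances.

The oracle for the full test is a deliberately plain, step-by-step
recomputation (centroids -> pooled covariance -> per-sample Mahalanobis
distance via scipy.spatial -> explicit sum-of-squares ANOVA), coded
independently of the package's vectorised path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg as sla
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis
from scipy.stats import f as f_dist

from dispervar import (
    GeneSetExpression,
    ValidationError,
    gk_contributions,
    mahalanobis_distances,
    md_dispersion_test,
    modified_transform,
    rank_geneset_contributions,
    scan_genesets,
)
from dispervar.md_dispersion import _group_distances
from dispervar.power_sim import default_config, simulate_dataset
from dispervar.synthetic import gen_geneset_matrix

from conftest import make_matrix


def oracle_dispersion_test(X0, X1, modified):
    """Independent step-by-step recomputation of the pooled-covariance test."""
    mu0 = X0.mean(axis=0)
    mu1 = X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    s = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n0 + n1 - 2)
    vi = np.linalg.inv(s)
    d0 = np.array([scipy_mahalanobis(x, mu0, vi) for x in X0])
    d1 = np.array([scipy_mahalanobis(x, mu1, vi) for x in X1])
    if modified:
        pooled = np.concatenate([d0, d1])
        t = np.percentile(pooled, 90)
        c = pooled.max()
        pooled = np.array([v * c if v > t else v for v in pooled])
        d0, d1 = pooled[:n0], pooled[n0:]
    grand = np.concatenate([d0, d1]).mean()
    ssb = n0 * (d0.mean() - grand) ** 2 + n1 * (d1.mean() - grand) ** 2
    ssw = ((d0 - d0.mean()) ** 2).sum() + ((d1 - d1.mean()) ** 2).sum()
    F = ssb / (ssw / (n0 + n1 - 2))
    return F, float(f_dist.sf(F, 1, n0 + n1 - 2))


def _gse(X0, X1, name="s"):
    return GeneSetExpression(name, [f"g{i}" for i in range(X0.shape[1])], X0, X1)


class TestMahalanobisDistances:
    def test_identity_covariance_is_euclidean(self, rng):
        X = rng.normal(size=(20, 4))
        center = rng.normal(size=4)
        d = mahalanobis_distances(X, center, np.eye(4))
        np.testing.assert_allclose(d, np.linalg.norm(X - center, axis=1), rtol=1e-12)

    def test_center_maps_to_zero(self):
        c = np.array([1.0, -2.0, 3.0])
        assert mahalanobis_distances(c[None, :], c, np.eye(3))[0] == 0.0

    def test_diagonal_case_analytic(self):
        d = mahalanobis_distances(np.array([[1.0, 2.0]]), np.zeros(2), np.diag([1.0, 4.0]))
        assert d[0] == pytest.approx(np.sqrt(2.0), abs=1e-12)


class TestModifiedTransform:
    def test_all_equal_unchanged(self):
        v = np.full(20, 3.0)
        np.testing.assert_array_equal(modified_transform(v), v)

    def test_hand_computed_example(self):
        # 1..10: linear-interpolation 90th percentile is 9.1; only 10 > 9.1,
        # boosted by the maximum (10) to 100
        v = np.arange(1.0, 11.0)
        out = modified_transform(v)
        expected = np.concatenate([np.arange(1.0, 10.0), [100.0]])
        np.testing.assert_allclose(out, expected)

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=80))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_body_below_percentile_preserved(self, vals):
        v = np.asarray(vals)
        t = np.percentile(v, 90)
        out = modified_transform(v)
        np.testing.assert_array_equal(out[v <= t], v[v <= t])
        assert out.shape == v.shape

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            modified_transform(np.array([-1.0, 2.0]))


class TestGKContributions:
    def test_diagonal_covariance_analytic(self):
        z = np.array([1.0, -2.0, 0.5])
        sigma = np.diag([1.0, 4.0, 0.25])
        np.testing.assert_allclose(gk_contributions(z, sigma), z ** 2 / np.diag(sigma), rtol=1e-12)

    def test_sum_equals_squared_md(self, rng):
        for _ in range(50):
            d = rng.integers(2, 8)
            a = rng.normal(size=(d + 3, d))
            sigma = a.T @ a / len(a) + 0.1 * np.eye(d)
            z = rng.normal(size=d)
            c = gk_contributions(z, sigma)
            assert (c >= 0).all()
            md2 = z @ np.linalg.solve(sigma, z)
            assert c.sum() == pytest.approx(md2, rel=1e-10)

    def test_matches_sqrtm_oracle(self):
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.array([1.0, 1.0])
        w_oracle = sla.sqrtm(np.linalg.inv(sigma))
        np.testing.assert_allclose(gk_contributions(z, sigma), (w_oracle @ z) ** 2, rtol=1e-9)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValidationError):
            gk_contributions(np.ones(2), np.ones((2, 2)))


class TestDispersionTest:
    def test_identical_groups_give_f_zero(self, rng):
        X = rng.normal(size=(40, 3))
        res = md_dispersion_test(_gse(X, X.copy()), variant="original")
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("variant", ["original", "modified"])
    def test_matches_stepwise_oracle(self, variant):
        rng = np.random.default_rng(42)
        X0 = rng.normal(size=(100, 5))
        X1 = 3.0 * rng.normal(size=(100, 5))
        res = md_dispersion_test(_gse(X0, X1), variant=variant)
        f, p = oracle_dispersion_test(X0, X1, modified=(variant == "modified"))
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10, abs=1e-300)

    @pytest.mark.parametrize("variant", ["original", "modified"])
    @pytest.mark.parametrize("mode", ["pooled", "per_group", "total"])
    def test_affine_invariance(self, variant, mode):
        rng = np.random.default_rng(3)
        X0 = rng.normal(size=(60, 4))
        X1 = rng.normal(size=(60, 4)) * 1.5
        base = md_dispersion_test(_gse(X0, X1), variant=variant, covariance_mode=mode)
        for _ in range(3):
            A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
            b = rng.normal(size=4)
            moved = md_dispersion_test(_gse(X0 @ A.T + b, X1 @ A.T + b),
                                       variant=variant, covariance_mode=mode)
            assert abs(moved.p_value - base.p_value) < 1e-8
            assert moved.f_statistic == pytest.approx(base.f_statistic, rel=1e-6)

    def test_label_swap_symmetry(self, rng):
        X0 = rng.normal(size=(50, 3))
        X1 = rng.normal(size=(50, 3)) * 2
        a = md_dispersion_test(_gse(X0, X1), variant="original")
        b = md_dispersion_test(_gse(X1, X0), variant="original")
        assert a.f_statistic == pytest.approx(b.f_statistic, rel=1e-10)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-10)

    def test_small_groups_rejected(self, rng):
        X0 = rng.normal(size=(5, 4))
        X1 = rng.normal(size=(50, 4))
        with pytest.raises(ValidationError):
            md_dispersion_test(_gse(X0, X1))

    def test_euclidean_metric_cross_check(self, rng):
        """With metric='euclidean' the distances are plain norms to centroids."""
        X0 = rng.normal(size=(30, 3))
        X1 = rng.normal(size=(30, 3))
        mdv = _group_distances(_gse(X0, X1), "pooled", "euclidean")
        np.testing.assert_allclose(mdv.D0, np.linalg.norm(X0 - X0.mean(0), axis=1), rtol=1e-12)


class TestContributionRanking:
    def test_shares_sum_to_one_and_sorted(self, rng):
        X0 = rng.normal(size=(40, 5))
        X1 = rng.normal(size=(40, 5))
        contrib = rank_geneset_contributions(_gse(X0, X1))
        shares = np.array([s for _, s in contrib])
        assert shares.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(shares) <= 1e-12).all()

    def test_symmetric_null_approaches_uniform(self):
        rng = np.random.default_rng(8)
        d = 4
        X0 = rng.normal(size=(4000, d))
        X1 = rng.normal(size=(4000, d))
        contrib = rank_geneset_contributions(_gse(X0, X1))
        for _, share in contrib:
            assert share == pytest.approx(1.0 / d, abs=0.05)

    def test_inflated_gene_ranks_first(self):
        rng = np.random.default_rng(9)
        X0 = rng.normal(size=(300, 6))
        X1 = rng.normal(size=(300, 6))
        X1[:, 2] *= np.sqrt(10)
        contrib = rank_geneset_contributions(_gse(X0, X1))
        assert contrib[0][0] == "g2"


class TestScanGenesets:
    def test_absent_genes_skip_set(self, rng):
        m = make_matrix(rng.normal(size=(6, 20)), n_case=10)
        from dispervar import GeneSetCollection

        sets = GeneSetCollection(sets={"absent": ["x1", "x2", "x3"]})
        assert scan_genesets(m, sets, min_genes=2) == []

    def test_duplicate_sets_identical_results(self, rng):
        m = make_matrix(rng.normal(size=(8, 60)), n_case=30)
        from dispervar import GeneSetCollection

        genes = [f"gene_{i:04d}" for i in range(8)]
        sets = GeneSetCollection(sets={"a": genes, "b": list(genes)})
        res = scan_genesets(m, sets, min_genes=2)
        assert res[0].f_statistic == pytest.approx(res[1].f_statistic, rel=1e-12)
        assert res[0].p_value == pytest.approx(res[1].p_value, rel=1e-12)

    def test_planted_sets_have_smallest_pvalues(self):
        cfg = default_config(d=8, seed=21)
        matrix, sets, truth = gen_geneset_matrix(cfg, n=250, n_planted_sets=3,
                                                 n_null_sets=10, alpha=3.0)
        results = scan_genesets(matrix, sets, min_genes=5)
        ranked = sorted(results, key=lambda r: r.p_value)
        top = {r.set_name for r in ranked[:3]}
        assert top == set(truth.loc[truth.planted, "set_name"])
        assert all(r.direction == "case" for r in ranked[:3])

    def test_empty_collection(self, rng):
        from dispervar import GeneSetCollection

        m = make_matrix(rng.normal(size=(4, 20)), n_case=10)
        assert scan_genesets(m, GeneSetCollection(sets={})) == []
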