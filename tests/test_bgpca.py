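"""Between-group PCA, projection, classification, typicality, HCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vestmorph import (
    BetweenGroupPCA,
    ShapeTable,
    SimConfig,
    fit_bgpca,
    hca_confusion,
    loo_classify,
    simulate_shape_sample,
)


def make_table(rng, means, n_per=10, sd=1.0, p=None):
    """Gaussian groups around supplied mean vectors."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    p = means.shape[1] if p is None else p
    rows, specimens, species, groups = [], [], [], []
    for g, mu in enumerate(means):
        for i in range(n_per):
            rows.append(mu + sd * rng.standard_normal(p))
            specimens.append(f"g{g}_s{i}")
            species.append(f"sp{g}")
            groups.append(f"G{g}")
    return ShapeTable.from_arrays(np.stack(rows), specimens, species, groups)


class TestFit:
    def test_two_groups_axis_forced_by_symmetry(self, rng):
        table = make_table(rng, [[0.0, 0.0], [2.0, 0.0]], n_per=5, sd=0.0)
        res = fit_bgpca(table)
        assert res.eigenvectors.shape == (2, 1)
        assert np.allclose(np.abs(res.eigenvectors[:, 0]), [1.0, 0.0])
        score = res.project(np.array([1.5, 7.0]))[0, 0]
        assert score == pytest.approx(0.5)  # grand mean at x=1

    def test_identical_means_flagged_degenerate(self, rng):
        table = make_table(rng, [[1.0, 2.0]] * 3, n_per=4, sd=0.0)
        res = fit_bgpca(table)
        assert res.degenerate
        assert np.allclose(res.eigenvalues, 0.0)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        """Eigenpairs equal brute-force eigh of the covariance of group means."""
        for _ in range(50):
            g = int(rng.integers(3, 6))
            p = int(rng.integers(5, 15))
            means = rng.standard_normal((g, p)) * 3
            table = make_table(rng, means, n_per=int(rng.integers(2, 6)), sd=1.0)
            res = fit_bgpca(table)
            X = table.X
            labels = sorted(set(table.groups))
            M = np.stack([X[table.groups.to_numpy() == gl].mean(axis=0) for gl in labels])
            S = np.cov(M.T, ddof=1) if p > 1 else np.atleast_2d(np.var(M, ddof=1))
            vals = np.linalg.eigvalsh(S)[::-1][: g - 1]
            assert np.abs(res.eigenvalues - np.clip(vals, 0, None)).max() < 1e-8
            # scores match projection onto eigh eigenvectors up to sign
            _, vecs = np.linalg.eigh(S)
            vecs = vecs[:, ::-1][:, : g - 1]
            ref = (X - M.mean(axis=0)) @ vecs
            got = res.scores[res.score_columns].to_numpy()
            for j in range(g - 1):
                assert (
                    np.abs(ref[:, j] - got[:, j]).max() < 1e-8
                    or np.abs(ref[:, j] + got[:, j]).max() < 1e-8
                )

    def test_at_most_g_minus_1_axes(self, rng):
        table = make_table(rng, rng.standard_normal((4, 30)), n_per=3)
        res = fit_bgpca(table)
        assert len(res.eigenvalues) == 3
        assert np.allclose(res.eigenvectors.T @ res.eigenvectors, np.eye(3), atol=1e-8)
        assert res.explained_var.sum() == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        table = make_table(rng, rng.standard_normal((4, 6)) * 3, n_per=6)
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        rotated = ShapeTable.from_arrays(
            table.X @ Q, list(table.specimens), list(table.species), list(table.groups)
        )
        r1, r2 = fit_bgpca(table), fit_bgpca(rotated)
        assert np.abs(r1.eigenvalues - r2.eigenvalues).max() < 1e-6
        s1 = r1.scores[r1.score_columns].to_numpy()
        s2 = r2.scores[r2.score_columns].to_numpy()
        for j in range(s1.shape[1]):
            assert min(
                np.abs(s1[:, j] - s2[:, j]).max(), np.abs(s1[:, j] + s2[:, j]).max()
            ) < 1e-6
        c1, c2 = r1.loo_classify(), r2.loo_classify()
        assert np.allclose(c1.confusion.to_numpy(), c2.confusion.to_numpy())


class TestProject:
    def test_grand_mean_and_training_idempotence(self, rng):
        table = make_table(rng, rng.standard_normal((3, 5)) * 2, n_per=5)
        res = fit_bgpca(table)
        assert np.abs(res.project(res.grand_mean)).max() < 1e-10
        assert np.abs(res.project(table.X) - res.scores[res.score_columns].to_numpy()).max() < 1e-10

    def test_out_of_span_query_is_fine(self, rng):
        table = make_table(rng, rng.standard_normal((3, 5)), n_per=5)
        res = fit_bgpca(table)
        far = res.grand_mean + 1e3
        assert np.all(np.isfinite(res.project(far)))

    def test_dimension_mismatch(self, rng):
        table = make_table(rng, rng.standard_normal((3, 5)), n_per=5)
        res = fit_bgpca(table)
        with pytest.raises(ValueError, match="descriptors"):
            res.project(np.zeros(4))


class TestLooClassify:
    def test_separated_groups_perfect(self, rng):
        means = np.zeros((2, 4))
        means[1, 0] = 50.0  # 10 sigma apart at sd=5
        table = make_table(rng, means, n_per=20, sd=5.0)
        assert loo_classify(table).accuracy == 100.0

    def test_identical_groups_near_chance(self, rng):
        table = make_table(rng, np.zeros((2, 4)), n_per=20, sd=1.0)
        res = loo_classify(table)
        assert 35.0 <= res.accuracy <= 65.0
        assert np.allclose(res.confusion.sum(axis=1), 100.0, atol=0.1)

    def test_single_specimen_group_rejected(self, rng):
        table = make_table(rng, np.zeros((2, 3)), n_per=1, sd=1.0)
        with pytest.raises(ValueError, match="G0"):
            loo_classify(table)

    def test_default_synthetic_geometry_highly_separable(self):
        table, _ = simulate_shape_sample(SimConfig(seed=5))
        res = loo_classify(table)
        assert res.accuracy >= 90.0

    def test_refit_variant_close_to_fixed_basis(self, rng):
        means = rng.standard_normal((3, 5)) * 8
        table = make_table(rng, means, n_per=8, sd=1.0)
        fixed = loo_classify(table)
        refit = loo_classify(table, refit=True)
        assert abs(fixed.accuracy - refit.accuracy) <= 15.0


class TestTypprob:
    def test_centroid_probability_one(self, rng):
        table = make_table(rng, rng.standard_normal((3, 5)) * 4, n_per=8)
        res = fit_bgpca(table)
        cents = res.group_centroids()
        p = res.typprob(cents.loc[["G0"]].to_numpy())
        assert p["G0"].iloc[0] == pytest.approx(1.0)

    def test_chi_square_quantile_identity(self, rng):
        """A query at the 95th chi-square percentile distance has p = 0.05."""
        table = make_table(rng, rng.standard_normal((4, 6)) * 4, n_per=50, sd=1.0)
        res = fit_bgpca(table)
        m = len(res.score_columns)
        W = res.pooled_within_cov()
        target_d2 = stats.chi2.ppf(0.95, df=m)
        cen = res.group_centroids().loc["G1"].to_numpy()
        direction = np.linalg.cholesky(W)[:, 0]
        q = cen + direction * np.sqrt(target_d2 / (direction @ np.linalg.inv(W) @ direction))
        p = res.typprob(q[None, :])
        assert p["G1"].iloc[0] == pytest.approx(0.05, abs=1e-9)

    def test_strictly_decreasing_in_distance(self, rng):
        table = make_table(rng, rng.standard_normal((3, 5)) * 4, n_per=10)
        res = fit_bgpca(table)
        cen = res.group_centroids().loc["G0"].to_numpy()
        direction = np.ones_like(cen)
        probs = [
            res.typprob((cen + t * direction)[None, :])["G0"].iloc[0]
            for t in np.linspace(0, 3, 7)
        ]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_f_variant_smaller_than_chisq_tail(self, rng):
        table = make_table(rng, rng.standard_normal((3, 4)) * 4, n_per=6)
        res = fit_bgpca(table)
        q = res.group_centroids().loc["G0"].to_numpy() + 2.0
        p_chi = res.typprob(q[None, :], method="chisq")["G0"].iloc[0]
        p_f = res.typprob(q[None, :], method="f")["G0"].iloc[0]
        assert 0 <= p_chi <= 1 and 0 <= p_f <= 1
        assert p_f != pytest.approx(p_chi)  # small-sample correction bites


class TestHCA:
    def test_tight_groups_fully_recovered(self, rng):
        means = np.eye(4) * 60
        table = make_table(rng, means, n_per=8, sd=1.0)
        probs = hca_confusion(table)
        assert np.allclose(probs.to_numpy(), 100.0)

    def test_overlapping_groups_bounded(self, rng):
        table = make_table(rng, np.zeros((2, 4)), n_per=10)
        probs = hca_confusion(table)
        assert ((probs >= 0) & (probs <= 100)).all()

    def test_intermediate_group_hardest(self, rng):
        """A group sitting between two others classifies worst."""
        means = np.array([[0.0, 0.0], [4.0, 0.0], [8.0, 0.0]])
        sums = pd.Series(0.0, index=["G0", "G1", "G2"])
        for rep in range(30):
            r = np.random.default_rng(1000 + rep)
            table = make_table(r, means, n_per=10, sd=2.0)
            sums += hca_confusion(table)
        assert sums["G1"] < sums["G0"]
        assert sums["G1"] < sums["G2"]

    def test_too_few_specimens_rejected(self, rng):
        table = make_table(rng, np.zeros((2, 3)), n_per=1)
        with pytest.raises(ValueError, match="at least"):
            hca_confusion(table, g=5)


def test_sklearn_reference_pca_on_group_means(rng):
    """Independent check: eigenvalues agree with scikit-learn PCA of the means."""
    from sklearn.decomposition import PCA

    means = rng.standard_normal((4, 8)) * 3
    table = make_table(rng, means, n_per=5)
    res = fit_bgpca(table)
    X = table.X
    labels = sorted(set(table.groups))
    M = np.stack([X[table.groups.to_numpy() == gl].mean(axis=0) for gl in labels])
    ref = PCA(n_components=3).fit(M)
    assert np.abs(ref.explained_variance_ - res.eigenvalues).max() < 1e-8
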