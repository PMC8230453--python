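"""PCA / group models / CVA / LDA / LOO against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from wingmorph.shapespace import (
    cva, fit_groups, lda_classify, loo_cross_validation,
    loo_cross_validation_refit_pca, mahalanobis_sq, mahalanobis_sq_point,
    pca, significant_dimensions,
)


class TestPca:
    def test_single_axis_of_variance(self):
        t = np.linspace(-1, 1, 11)
        X = np.outer(t, np.array([3.0, 4.0, 0.0]))
        space = pca(X, k=3)
        assert significant_dimensions(space) == 1

    def test_reconstruction_from_full_basis(self, rng):
        X = rng.normal(size=(20, 6))
        space = pca(X, k=6)
        recon = space.scores @ space.basis.T + space.mean_vector
        assert np.allclose(recon, X, atol=1e-8)

    def test_eigenvalues_match_dense_eigensolver_oracle(self, rng):
        X = rng.normal(size=(40, 8))
        space = pca(X, k=8)
        # independent oracle: direct covariance eigendecomposition
        C = np.cov(X, rowvar=False, ddof=1)
        expected = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(space.eigenvalues, expected, atol=1e-10)
        assert np.allclose(space.basis.T @ space.basis, np.eye(8), atol=1e-10)

    def test_total_score_variance_equals_eigenvalue_sum(self, rng):
        X = rng.normal(size=(30, 5))
        space = pca(X, k=5)
        total = np.var(space.scores, axis=0, ddof=1).sum()
        assert total == pytest.approx(space.eigenvalues.sum())

    def test_k_beyond_rank_truncated_with_warning(self, rng):
        X = rng.normal(size=(4, 10))  # rank at most 3
        with pytest.warns(UserWarning, match="rank"):
            space = pca(X, k=10)
        assert space.k == 3


class TestGroupModel:
    def test_means_and_pooled_covariance_match_brute_force(self, rng):
        X = rng.normal(size=(25, 4))
        labels = list("aabb" * 6) + ["a"]
        model = fit_groups(X, labels)
        for g in ("a", "b"):
            rows = X[np.array(labels) == g]
            assert np.allclose(model.means[model.index_of(g)], rows.mean(axis=0))
        # brute-force pooled covariance loop
        W = np.zeros((4, 4))
        for g in ("a", "b"):
            rows = X[np.array(labels) == g]
            mu = rows.mean(axis=0)
            for r in rows:
                W += np.outer(r - mu, r - mu)
        assert np.allclose(model.pooled_covariance, W / (25 - 2), atol=1e-12)

    def test_zero_within_variance_flags_singular(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        model = fit_groups(X, ["a", "a", "b", "b"])
        assert model.singular
        assert model.means[:, 0].tolist() == [0.0, 2.0]

    def test_unknown_group_raises(self, rng):
        model = fit_groups(rng.normal(size=(10, 2)), list("ababababab"))
        with pytest.raises(KeyError, match="zzz"):
            mahalanobis_sq(model, "a", "zzz")


class TestMahalanobis:
    def test_one_dimensional_closed_form(self):
        # means 0 and 3 with pooled within-group variance exactly 1 -> D^2 = 9
        h = np.sqrt(0.5)  # each group contributes SS = 1, pooled df = 2
        X = np.array([-h, h, 3 - h, 3 + h])[:, None]
        model = fit_groups(X, ["a", "a", "b", "b"])
        assert model.pooled_covariance[0, 0] == pytest.approx(1.0)
        assert mahalanobis_sq(model, "a", "b") == pytest.approx(9.0)

    def test_identity_covariance_gives_squared_euclidean(self, rng):
        mu = rng.normal(size=(2, 5))
        n = 4000
        X = np.vstack([
            mu[0] + rng.normal(size=(n, 5)), mu[1] + rng.normal(size=(n, 5)),
        ])
        model = fit_groups(X, ["a"] * n + ["b"] * n)
        expected = float(np.sum((model.means[0] - model.means[1]) ** 2))
        assert mahalanobis_sq(model, "a", "b") == pytest.approx(expected, rel=0.05)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(60, 4))
        labels = ["a"] * 30 + ["b"] * 30
        X[30:] += 1.5
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        shift = rng.normal(size=4)
        m1 = fit_groups(X, labels)
        m2 = fit_groups(X @ A + shift, labels)
        assert mahalanobis_sq(m1, "a", "b") == pytest.approx(
            mahalanobis_sq(m2, "a", "b"), rel=1e-8
        )

    def test_symmetry_and_zero_diagonal(self, rng):
        X = rng.normal(size=(30, 3))
        labels = ["a", "b", "c"] * 10
        model = fit_groups(X, labels)
        assert mahalanobis_sq(model, "a", "a") == 0.0
        assert mahalanobis_sq(model, "a", "c") == pytest.approx(
            mahalanobis_sq(model, "c", "a")
        )

    def test_unbiased_correction_centres_on_truth(self, rng):
        # two spherical groups at known D^2 = 4; the corrected estimator
        # should average near 4 while the plain one sits above it
        plain, corrected = [], []
        for seed in range(30):
            r = np.random.default_rng(seed)
            X = np.vstack([
                r.normal(size=(25, 8)),
                r.normal(size=(25, 8)) + np.r_[2.0, np.zeros(7)],
            ])
            model = fit_groups(X, ["a"] * 25 + ["b"] * 25)
            plain.append(mahalanobis_sq(model, "a", "b"))
            corrected.append(mahalanobis_sq(model, "a", "b", unbiased=True))
        assert np.mean(plain) > 4.0
        assert np.mean(corrected) == pytest.approx(4.0, rel=0.15)


class TestCva:
    def test_two_groups_single_axis(self, rng):
        X = rng.normal(size=(40, 6))
        labels = ["a"] * 20 + ["b"] * 20
        X[20:] += 2.0
        model = fit_groups(X, labels)
        res = cva(model, X, labels)
        assert res.canonical_axes.shape == (6, 1)
        assert res.canonical_eigenvalues.shape == (1,)

    def test_six_groups_structure(self, rng):
        X = rng.normal(size=(120, 8))
        labels = [f"g{i % 6}" for i in range(120)]
        for i in range(120):
            X[i, i % 6 % 8] += 3 * (i % 6)
        model = fit_groups(X, labels)
        res = cva(model, X, labels)
        assert res.canonical_axes.shape[1] == 5
        D = res.squared_mahalanobis.to_numpy()
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)
        assert (D[~np.eye(6, dtype=bool)] > 0).all()

    def test_pairwise_distances_match_mahalanobis_sq(self, rng):
        X = rng.normal(size=(45, 5))
        labels = ["a", "b", "c"] * 15
        model = fit_groups(X, labels)
        res = cva(model, X, labels)
        for g1 in "abc":
            for g2 in "abc":
                assert res.squared_mahalanobis.loc[g1, g2] == pytest.approx(
                    mahalanobis_sq(model, g1, g2), abs=1e-12
                )

    def test_two_group_axis_is_fisher_direction(self, rng):
        X = rng.normal(size=(60, 4))
        labels = ["a"] * 30 + ["b"] * 30
        X[30:, 0] += 3.0
        model = fit_groups(X, labels)
        res = cva(model, X, labels)
        fisher = scipy.linalg.solve(
            model.pooled_covariance, model.means[0] - model.means[1]
        )
        a = res.canonical_axes[:, 0]
        cos = abs(fisher @ a) / (np.linalg.norm(fisher) * np.linalg.norm(a))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_axes_whiten_within_covariance(self, rng):
        X = rng.normal(size=(90, 5))
        labels = ["a", "b", "c"] * 30
        X[np.array(labels) == "b"] += [1, 0, 0, 0, 0]
        X[np.array(labels) == "c"] += [0, 2, 0, 0, 0]
        model = fit_groups(X, labels)
        res = cva(model, X, labels)
        A = res.canonical_axes
        assert np.allclose(A.T @ model.pooled_covariance @ A, np.eye(A.shape[1]),
                           atol=1e-8)


class TestLdaClassify:
    def test_group_mean_classifies_to_its_group(self, rng):
        X = rng.normal(size=(30, 3))
        labels = ["a", "b", "c"] * 10
        X[np.array(labels) == "b"] += 4
        model = fit_groups(X, labels)
        for g in "abc":
            label, post = lda_classify(model, model.means[model.index_of(g)])
            assert label == g
            assert post[g] == max(post.values())

    def test_exact_tie_warns_and_takes_first(self, rng, caplog):
        X = np.array([[0.0, 1.0], [0.0, -1.0], [4.0, 1.0], [4.0, -1.0]])
        model = fit_groups(X, ["a", "a", "b", "b"])
        with caplog.at_level("WARNING"):
            label, _ = lda_classify(model, np.array([2.0, 0.0]))
        assert label == "a"
        assert "tie" in caplog.text

    def test_matches_brute_force_discriminant_evaluation(self, rng):
        X = rng.normal(size=(60, 4))
        labels = ["a", "b", "c"] * 20
        X[np.array(labels) == "b"] += 1.0
        model = fit_groups(X, labels)
        Sinv = np.linalg.inv(model.pooled_covariance)
        for _ in range(25):
            x = rng.normal(size=4)
            d2 = [ (x - m) @ Sinv @ (x - m) for m in model.means ]
            expected = model.labels[int(np.argmin(d2))]
            assert lda_classify(model, x)[0] == expected


def _brute_force_loo(X, labels):
    """Independent LOO oracle: refit means and pooled covariance per fold."""
    labels = np.asarray(labels, dtype=object)
    correct = 0
    n = len(X)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, li = X[keep], labels[keep]
        uniq = list(dict.fromkeys(li))
        means = {g: Xi[li == g].mean(axis=0) for g in uniq}
        W = sum(
            ((Xi[li == g] - means[g]).T @ (Xi[li == g] - means[g])) for g in uniq
        )
        S = W / (len(Xi) - len(uniq))
        Sinv = np.linalg.pinv(S)
        d2 = {g: (X[i] - means[g]) @ Sinv @ (X[i] - means[g]) for g in uniq}
        pred = min(uniq, key=lambda g: d2[g])
        correct += pred == labels[i]
    return 100.0 * correct / n


class TestLoo:
    def test_widely_separated_groups_are_perfect(self, rng):
        X = np.vstack([rng.normal(size=(15, 3)), rng.normal(size=(15, 3)) + 30])
        rate, table = loo_cross_validation(X, ["a"] * 15 + ["b"] * 15)
        assert rate == 100.0
        assert table["correct"].all()

    def test_permuted_labels_near_chance(self):
        r = np.random.default_rng(99)
        X = np.vstack([r.normal(size=(50, 3)), r.normal(size=(50, 3)) + 5])
        labels = np.array(["a"] * 50 + ["b"] * 50)
        r.shuffle(labels)
        rate, _ = loo_cross_validation(X, labels)
        # chance level 50%, binomial sd ~5% -> generous 4-sigma band
        assert 30.0 <= rate <= 70.0

    def test_rate_equals_brute_force_refit_oracle(self, rng):
        X = rng.normal(size=(24, 3))
        labels = ["a", "b", "c"] * 8
        X[np.array(labels) == "c"] += 1.5
        rate, _ = loo_cross_validation(X, labels)
        assert rate == pytest.approx(_brute_force_loo(X, labels), abs=1e-9)

    def test_singleton_group_skipped_with_warning(self, rng, caplog):
        X = rng.normal(size=(7, 2))
        labels = ["a", "a", "a", "b", "b", "b", "c"]
        with caplog.at_level("WARNING"):
            rate, table = loo_cross_validation(X, labels)
        assert table["predicted"].isna().sum() == 1
        assert "skipped" in caplog.text

    def test_refit_pca_variant_agrees_on_clear_structure(self, rng):
        X = np.vstack([rng.normal(size=(12, 6)), rng.normal(size=(12, 6)) + 10])
        labels = ["a"] * 12 + ["b"] * 12
        rate_fixed, _ = loo_cross_validation(pca(X, k=5).scores, labels)
        rate_refit, _ = loo_cross_validation_refit_pca(X, labels, k=5)
        assert rate_fixed == rate_refit == 100.0
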