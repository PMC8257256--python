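"""Ensemble statistics: k-NN estimators, PCA, significance, centroid
geometry, bootstrap/shuffle inference and the manifold-decay fit."""

import numpy as np
import pytest

from discmorph.errors import DiscmorphError, EstimatorError
from discmorph.stats import (
    GroupComparison,
    alignment_cosine,
    bootstrap_alignment_curve,
    centroid_difference_map,
    count_significant_eigenvalues,
    dequantize,
    entropy_map,
    fit_manifold_decay,
    knn_entropy,
    knn_kl_divergence,
    orthogonal_residual,
    pca_decompose,
    shuffle_null_pvalue,
    symmetrized_kl_map,
)

GAUSS_H = 0.5 * np.log(2 * np.pi * np.e)


class TestKnnEntropy:
    def test_gaussian_closed_form(self):
        vals = [knn_entropy(np.random.default_rng(s).standard_normal(5000), 3)
                for s in range(5)]
        assert np.median(vals) == pytest.approx(GAUSS_H, abs=0.05)

    def test_uniform_closed_form(self):
        vals = [knn_entropy(np.random.default_rng(s).uniform(0, 1, 5000), 3)
                for s in range(5)]
        assert np.median(vals) == pytest.approx(0.0, abs=0.05)

    def test_scaling_law(self):
        x = np.random.default_rng(0).standard_normal(4000)
        assert knn_entropy(10 * x, 3) - knn_entropy(x, 3) == pytest.approx(np.log(10), abs=0.02)

    def test_2d_gaussian(self):
        x = np.random.default_rng(1).standard_normal((6000, 2))
        assert knn_entropy(x, 3) == pytest.approx(2 * GAUSS_H, abs=0.1)

    def test_duplicates_rejected_with_hint(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(EstimatorError, match="dequantize"):
            knn_entropy(x, 1)

    def test_psi_variant_close_for_large_n(self):
        x = np.random.default_rng(2).standard_normal(2000)
        a = knn_entropy(x, 3, n_term="log_nm1")
        b = knn_entropy(x, 3, n_term="psi")
        assert abs(a - b) < 0.01
        assert a != b

    def test_estimator_consistency(self):
        errs = []
        for n in (500, 2000, 8000):
            vals = [knn_entropy(np.random.default_rng(100 * s + n).standard_normal(n), 3)
                    for s in range(10)]
            errs.append(abs(np.median(vals) - GAUSS_H))
        assert errs[2] <= errs[0]


class TestKnnKL:
    def test_same_distribution_is_zero(self):
        rng = np.random.default_rng(0)
        assert knn_kl_divergence(rng.standard_normal(3000), rng.standard_normal(3000), 2) == \
            pytest.approx(0.0, abs=0.05)

    def test_mean_shift_closed_form(self):
        rng = np.random.default_rng(1)
        d = knn_kl_divergence(rng.standard_normal(3000), rng.standard_normal(3000) + 1.0, 2)
        assert d == pytest.approx(0.5, abs=0.1)

    def test_asymmetry_with_scale_mismatch(self):
        # closed forms: KL(N(0,1)||N(0,4)) = ln2 + 1/8 - 1/2 = 0.3181,
        #               KL(N(0,4)||N(0,1)) = -ln2 + 2 - 1/2 = 0.8069.
        # The k-NN estimate of the wide-into-narrow direction carries a
        # known finite-n downward bias, so it is bounded rather than pinned.
        rng = np.random.default_rng(2)
        x = rng.standard_normal(3000)
        y = 2.0 * rng.standard_normal(3000)
        d_xy = knn_kl_divergence(x, y, 2)
        d_yx = knn_kl_divergence(y, x, 2)
        assert d_xy == pytest.approx(np.log(2) + 1 / 8 - 0.5, abs=0.1)
        assert 0.45 < d_yx < 0.95
        assert d_yx > d_xy + 0.15

    def test_zero_distances_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 3.0, 5.0])  # duplicate pair gives nu_2 = 0
        with pytest.raises(EstimatorError, match="dequantize"):
            knn_kl_divergence(y, y.copy(), 2)
        with pytest.raises(EstimatorError):
            knn_kl_divergence(x, np.array([2.0, 2.0, 2.0, 5.0]), 2)


class TestEntropyMap:
    def test_constant_column_flagged_at_jitter_floor(self):
        rng = np.random.default_rng(0)
        X = np.c_[np.full(200, 77.0), rng.normal(100, 20, 200)]
        em = entropy_map(X, k=3, seed=1)
        assert em.minimal[0] and not em.minimal[1]
        # Uniform(-1/2, 1/2) jitter has differential entropy 0
        assert em.values[0] == pytest.approx(0.0, abs=0.1)

    def test_gaussian_column_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(100, 20, (200, 30))
        em = entropy_map(X, k=3, seed=0)
        target = 0.5 * np.log(2 * np.pi * np.e * 400)
        assert np.median(em.values) == pytest.approx(target, abs=0.1)

    def test_exchangeable_columns_agree(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 5, (200, 2))
        em = entropy_map(X, k=3, seed=3)
        assert abs(em.values[0] - em.values[1]) < 0.15

    def test_matches_general_estimator_per_column(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 3, (60, 4))
        Xj = dequantize(X, 5)
        em_vals = entropy_map(X, k=3, seed=5).values
        direct = [knn_entropy(Xj[:, c], 3) for c in range(4)]
        assert np.allclose(em_vals, direct, atol=1e-10)

    def test_too_few_images_rejected(self):
        with pytest.raises(EstimatorError):
            entropy_map(np.random.default_rng(0).normal(size=(10, 3)))


class TestSymmetrizedKLMap:
    def test_identical_distributions_near_zero(self):
        # independent draws from one distribution; literally duplicated
        # samples violate the estimator's independence assumption and are
        # rejected (checked below)
        rng = np.random.default_rng(0)
        A = rng.normal(100, 10, (500, 12))
        B = rng.normal(100, 10, (500, 12))
        m = symmetrized_kl_map(A, B, seed=1)
        assert abs(m.mean()) < 0.05
        assert np.abs(m).max() < 0.2
        with pytest.raises(EstimatorError, match="independent"):
            symmetrized_kl_map(A, A.copy(), seed=None)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        A = rng.normal(100, 5, (150, 60))
        B = rng.normal(100, 5, (150, 60))
        B[:, 7] += 15.0  # 3 sigma shift in one column
        m = symmetrized_kl_map(A, B, seed=2)
        rest = np.delete(m, 7)
        assert m[7] > np.quantile(rest, 0.99)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(2)
        A = rng.normal(0, 1, (80, 10))
        B = rng.normal(0.5, 1, (80, 10))
        # swapping the (pre-jittered) ensembles leaves the map unchanged
        Aj = dequantize(A, 3)
        Bj = dequantize(B, 4)
        m1 = symmetrized_kl_map(Aj, Bj, seed=None)
        m2 = symmetrized_kl_map(Bj, Aj, seed=None)
        assert np.allclose(m1, m2)


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(40)
        u /= np.linalg.norm(u)
        X = np.outer(rng.standard_normal(100), u) + 1e-3 * rng.standard_normal((100, 40))
        r = pca_decompose(X)
        assert r.explained_fraction[0] > 0.99

    def test_isotropic_cloud_no_dominant_mode(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((2000, 50))
        r = pca_decompose(X, 50)
        # Marchenko-Pastur edge for d/n = 0.025 is (1 + sqrt(0.025))^2 = 1.34
        assert r.eigenvalues[0] / r.eigenvalues.mean() < 1.5

    def test_planted_direction_recovery(self):
        rng = np.random.default_rng(2)
        d = 60
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        t = rng.standard_normal(300) * np.sqrt(10 * d)  # Var(t) = 10 * d * Var(eps)
        X = np.outer(t, u) + rng.standard_normal((300, d))
        r = pca_decompose(X, 5)
        assert abs(np.dot(r.components[0], u)) > 0.95

    def test_orthonormal_and_ordered(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 20)) * np.linspace(5, 1, 20)
        r = pca_decompose(X, 10)
        G = r.components @ r.components.T
        assert np.allclose(G, np.eye(10), atol=1e-8)
        assert np.all(np.diff(r.eigenvalues) <= 1e-12)
        assert r.explained_fraction.sum() <= 1 + 1e-12

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 8))
        r = pca_decompose(X, 3)
        for comp in r.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_component_count_validated(self):
        X = np.random.default_rng(0).standard_normal((10, 5))
        with pytest.raises(DiscmorphError):
            pca_decompose(X, 10)


class TestEigenvalueSignificance:
    def test_null_calibration_on_independent_noise(self):
        rng = np.random.default_rng(0)
        counts = []
        for rep in range(5):
            X = rng.standard_normal((40, 60))
            c, _, _ = count_significant_eigenvalues(X, n_resamples=60, seed=rep)
            counts.append(c)
        k = min(40 - 1, 60)
        assert np.mean(counts) <= 0.05 * k + 1

    def test_planted_factors_recovered(self):
        rng = np.random.default_rng(1)
        n, d, nf = 60, 80, 5
        F = rng.standard_normal((n, nf)) * 6.0
        L = rng.standard_normal((nf, d))
        X = F @ L + rng.standard_normal((n, d))
        c, _, _ = count_significant_eigenvalues(X, n_resamples=60, seed=2)
        assert c >= nf

    def test_shuffled_observed_matches_null(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 50))
        perm = np.argsort(rng.random(X.shape), axis=0)
        Xs = np.take_along_axis(X, perm, axis=0)
        _, obs, null = count_significant_eigenvalues(Xs, n_resamples=100, seed=4)
        ks = ks_2samp(obs, null.ravel())
        assert ks.pvalue > 0.01


class TestCentroidGeometry:
    def test_identical_groups_zero_delta(self):
        X = np.random.default_rng(0).standard_normal((20, 10))
        comp = GroupComparison.between(X, X.copy())
        assert comp.distance == 0.0

    def test_constant_offset_closed_form(self):
        X = np.random.default_rng(1).standard_normal((20, 16))
        comp = GroupComparison.between(X, X + 3.0)
        assert comp.distance == pytest.approx(3.0 * np.sqrt(16))
        assert np.allclose(comp.delta, 3.0)

    def test_cosine_trivial_cases(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 30))
        r = pca_decompose(X, 6)
        comp = GroupComparison.between(X, X + 2.0 * r.components[0])
        assert alignment_cosine(comp, r, 1) == pytest.approx(1.0, abs=1e-10)
        # direction orthogonal to PC1..PC4
        comp5 = GroupComparison.between(X, X + 2.0 * r.components[5])
        for k in range(1, 5):
            assert alignment_cosine(comp5, r, k) == pytest.approx(0.0, abs=1e-10)

    def test_random_direction_null_scale(self):
        rng = np.random.default_rng(3)
        d = 1000
        X = rng.standard_normal((30, d))
        r = pca_decompose(X, 2)
        hits = 0
        for _ in range(40):
            delta = rng.standard_normal(d)
            comp = GroupComparison(delta=delta, distance=np.linalg.norm(delta),
                                   direction=delta / np.linalg.norm(delta))
            if alignment_cosine(comp, r, 1) < 0.08:
                hits += 1
        assert hits >= 0.95 * 40 - 3

    def test_zero_distance_cosine_undefined(self):
        X = np.random.default_rng(4).standard_normal((20, 5))
        r = pca_decompose(X, 2)
        with pytest.raises(DiscmorphError):
            alignment_cosine(GroupComparison.between(X, X.copy()), r, 1)

    def test_geometry_identity_exact(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 25))
        Y = X + rng.standard_normal(25) * 0.7
        r = pca_decompose(X, 4)
        comp = GroupComparison.between(X, Y)
        cos = alignment_cosine(comp, r, 1)
        lhs = np.sqrt(1 - cos**2) * comp.distance
        assert lhs == pytest.approx(orthogonal_residual(comp, r), abs=1e-8)


class TestBootstrapShuffle:
    def _cylinder(self, rng, n=120, d=20, R=10.0, sigma=None, spread=5.0):
        # orthogonal noise of total norm ~1 (sigma/R = 0.1 at R = 10)
        if sigma is None:
            sigma = 1.0 / np.sqrt(d)
        u = np.zeros(d)
        u[0] = 1.0
        A = rng.standard_normal(n)[:, None] * spread * u + sigma * rng.standard_normal((n, d))
        B = (R * u + rng.standard_normal(n)[:, None] * spread * u
             + sigma * rng.standard_normal((n, d)))
        return A, B

    def test_identical_groups_near_noise_floor(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 40))
        pts = bootstrap_alignment_curve(X, X.copy(), n_boot=30, seed=1)
        # R clusters near the subsampling noise floor sqrt(2 * d / m)
        m = 30
        floor = np.sqrt(2 * 40 / m)
        assert np.median(pts[:, 0]) < 3 * floor
        # and the cosine sits at the 1/sqrt(d) null scale, not near 1
        assert np.median(pts[:, 1]) < 5 / np.sqrt(40)

    def test_planted_displacement_high_cosine(self):
        rng = np.random.default_rng(1)
        A, B = self._cylinder(rng, R=10.0)
        pts = bootstrap_alignment_curve(A, B, n_boot=30, seed=2)
        assert pts[:, 1].mean() >= 0.99

    def test_bootstrap_stability_in_n_boot(self):
        rng = np.random.default_rng(2)
        A, B = self._cylinder(rng, R=10.0)
        r1 = bootstrap_alignment_curve(A, B, n_boot=60, seed=3)[:, 0].mean()
        r2 = bootstrap_alignment_curve(A, B, n_boot=120, seed=4)[:, 0].mean()
        assert abs(r2 - r1) / r1 < 0.02

    def test_invalid_frac_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 5))
        with pytest.raises(DiscmorphError):
            bootstrap_alignment_curve(X, X, frac=1.5)

    def test_shuffle_p_small_for_planted_signal(self):
        # strong displacement in a high-dimensional phenotype space: null
        # directions decorrelate at the 1/sqrt(d) scale
        rng = np.random.default_rng(3)
        d = 300
        u = np.zeros(d)
        u[0] = 1.0
        A = rng.standard_normal(80)[:, None] * 3 * u + rng.standard_normal((80, d))
        B = 5 * u + rng.standard_normal(80)[:, None] * 3 * u + rng.standard_normal((80, d))
        X = np.vstack([A, B])
        labels = np.array(["a"] * len(A) + ["b"] * len(B))
        p, obs, null = shuffle_null_pvalue(X, labels, "a", "b", n_shuffles=99, seed=4)
        assert p <= 1 / (99 + 1)
        assert obs > np.max(null)

    def test_zero_shuffles_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 5))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.raises(DiscmorphError):
            shuffle_null_pvalue(X, labels, "a", "b", n_shuffles=0)

    def test_strata_preserved(self):
        rng = np.random.default_rng(5)
        n = 40
        X = rng.standard_normal((2 * n, 20))
        X[n:, 1] += 5.0  # sex effect in stratum 2
        labels = np.array((["a"] * (n // 2) + ["b"] * (n // 2)) * 2)
        strata = np.array(["F"] * n + ["M"] * n)
        p, _, null = shuffle_null_pvalue(X, labels, "a", "b", strata=strata,
                                         n_shuffles=50, seed=6)
        assert np.isfinite(null).all()
        assert 0 < p <= 1

    def test_null_centered(self):
        rng = np.random.default_rng(6)
        d = 200
        X = rng.standard_normal((80, d))
        labels = np.array(["a"] * 40 + ["b"] * 40)
        _, _, null = shuffle_null_pvalue(X, labels, "a", "b", n_shuffles=60, seed=7)
        assert np.mean(null) < 3 / np.sqrt(d) * 3


class TestManifoldFit:
    def test_cylinder_alpha_one(self):
        # exact cylinder geometry: sqrt(1 - cos^2) = sigma / R with fixed sigma
        rng = np.random.default_rng(0)
        sigma = 2.0
        R = sigma * np.exp(rng.uniform(0.5, 3, 40))
        cos = np.sqrt(1 - (sigma / R) ** 2)
        fit = fit_manifold_decay(np.c_[R, cos])
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_cone_alpha_zero(self):
        rng = np.random.default_rng(1)
        R = np.exp(rng.uniform(0, 3, 40))
        cos = np.full_like(R, 1 / np.sqrt(2))  # sigma proportional to R
        fit = fit_manifold_decay(np.c_[R, cos])
        assert fit.alpha == pytest.approx(0.0, abs=0.05)

    def test_constant_cosine_zero_slope(self):
        R = np.linspace(1, 50, 20)
        fit = fit_manifold_decay(np.c_[R, np.full(20, 0.6)])
        assert fit.alpha == pytest.approx(0.0, abs=1e-10)

    def test_cylinder_prediction_line(self):
        R = np.array([2.0, 4.0, 8.0, 16.0, 32.0])
        sigma = 1.5
        cos = np.sqrt(1 - (sigma / R) ** 2)
        fit = fit_manifold_decay(np.c_[R, cos])
        pred = fit.cylinder_prediction(R)
        assert np.allclose(pred, sigma / R, rtol=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DiscmorphError):
            fit_manifold_decay(np.c_[np.ones(6), np.ones(6)])
        with pytest.raises(DiscmorphError):
            fit_manifold_decay(np.c_[np.zeros(6), 0.5 * np.ones(6)])


class TestCentroidDifferenceMap:
    def test_planted_vein_shift_localizes(self):
        # two ensembles of disc images differing by one displaced dark bar
        from discmorph.alignment import AlignedEnsemble, MobiusParams
        from discmorph.conformal import DiscImage, DiscMaskSpec, disc_pixel_mask
        from discmorph.radon import ensemble_to_matrix, default_angles

        D = 64
        spec = DiscMaskSpec(D)
        valid = disc_pixel_mask(spec)
        c = spec.pixel_centers()
        rng = np.random.default_rng(0)

        def bar_image(x0, seed):
            g = 150.0 - 60 * np.exp(-((c.real - x0) ** 2) / 0.004)
            g += np.random.default_rng(seed).normal(0, 2, (D, D))
            g[~valid] = 0
            return g

        def ens(x0, seeds):
            imgs = [DiscImage(bar_image(x0, s), valid, {"image_id": f"{x0}_{s}"}) for s in seeds]
            return AlignedEnsemble(images=imgs, reference_id=imgs[0].provenance["image_id"],
                                   params={}, scores={})

        angles = default_angles(3.0)
        A = ensemble_to_matrix(ens(-0.15, range(12)), angles)
        B = ensemble_to_matrix(ens(0.15, range(100, 112)), angles)
        comp, img = centroid_difference_map(A, B)
        assert comp.distance > 0
        mag = np.abs(img.grid[valid])
        top = mag >= np.quantile(mag, 0.9)
        support = (np.abs(c.real) < 0.25)[valid]  # both bar positions
        frac = (top & support).sum() / top.sum()
        assert frac > 0.5
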