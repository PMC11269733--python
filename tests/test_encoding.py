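"""Voxelwise encoding: PCA compression, OLS fit, evaluation, contrasts."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from vidbold import encoding
from vidbold.encoding import (
    EncodingResult,
    InsufficientRankError,
    average_encoding_results,
    contrast_feature_sets,
    fit_encode_predict,
    noise_normalize,
    prepare_features,
)
from vidbold.reliability import ReliabilityMap


class TestPrepareFeatures:
    def test_full_rank_transform_preserves_distances(self, rng):
        train = rng.standard_normal((200, 100))
        test = rng.standard_normal((30, 100))
        tr, te = prepare_features(train, test, n_components=100, standardize=False)
        # PCA on full-rank features is a centered rotation
        assert np.allclose(pdist(tr), pdist(train), atol=1e-10)
        assert np.allclose(pdist(te), pdist(test), atol=1e-10)

    def test_rank_deficient_features_rejected(self, rng):
        low = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 120))
        with pytest.raises(InsufficientRankError):
            prepare_features(low, low[:10], n_components=100)
        with pytest.raises(InsufficientRankError):
            prepare_features(rng.standard_normal((50, 200)), rng.standard_normal((5, 200)), n_components=100)

    def test_explained_variance_matches_eigendecomposition(self, rng):
        train = rng.standard_normal((300, 40)) @ rng.standard_normal((40, 60))
        train += 0.1 * rng.standard_normal(train.shape)
        mu, sd = train.mean(0), train.std(0)
        z = (train - mu) / sd
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(z.T)))[::-1]
        tr, _ = prepare_features(train, train[:5], n_components=20)
        component_var = tr.var(axis=0, ddof=1)
        assert np.allclose(component_var, eigvals[:20], atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        train = rng.standard_normal((80, 30))
        test = rng.standard_normal((10, 30))
        a = prepare_features(train, test, n_components=10)
        b = prepare_features(train.copy(), test.copy(), n_components=10)
        assert np.allclose(a[0], b[0]) and np.allclose(a[1], b[1])


class TestFitEncodePredict:
    def test_noiseless_linear_ground_truth_perfect(self, rng):
        X = rng.standard_normal((100, 8))
        Xte = rng.standard_normal((20, 8))
        W = rng.standard_normal((8, 30))
        test_betas = np.repeat((Xte @ W)[:, None, :], 10, axis=1)
        res = fit_encode_predict(X, X @ W, Xte, test_betas)
        assert np.nanmin(res.raw) > 1 - 1e-9

    def test_unrelated_features_near_zero(self, rng):
        X = rng.standard_normal((150, 10))
        Xte = rng.standard_normal((40, 10))
        betas = rng.standard_normal((150, 500))
        test_betas = rng.standard_normal((40, 10, 500))
        res = fit_encode_predict(X, betas, Xte, test_betas)
        assert abs(np.nanmean(res.raw)) < 0.05

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((60, 6))
        Y = rng.standard_normal((60, 20))
        Xte = rng.standard_normal((12, 6))
        X1 = np.column_stack([np.ones(60), X])
        Xte1 = np.column_stack([np.ones(12), Xte])
        oracle = np.column_stack(
            [Xte1 @ np.linalg.solve(X1.T @ X1, X1.T @ Y[:, v]) for v in range(20)]
        )
        pred = encoding._ols_fit_predict(X, Y, Xte)
        assert np.max(np.abs(pred - oracle)) < 1e-8

    def test_voxel_mask_restricts_prediction(self, rng):
        X = rng.standard_normal((50, 4))
        Y = rng.standard_normal((50, 10))
        Xte = rng.standard_normal((8, 4))
        test_betas = rng.standard_normal((8, 10, 10))
        mask = np.zeros(10, bool)
        mask[:4] = True
        res = fit_encode_predict(X, Y, Xte, test_betas, voxel_mask=mask)
        assert np.isfinite(res.raw[:4]).all() and np.isnan(res.raw[4:]).all()

    def test_repetition_average_vs_mean_correlation_differ_under_noise(self, rng):
        # correlating against each repetition then averaging is not the same
        # as correlating against the repetition mean, except when noiseless
        X = rng.standard_normal((200, 5))
        Xte = rng.standard_normal((50, 5))
        W = rng.standard_normal((5, 1))
        clean = Xte @ W
        test_betas = clean[:, None, :] + rng.standard_normal((50, 10, 1))
        res_reps = fit_encode_predict(X, X @ W, Xte, test_betas)
        res_mean = fit_encode_predict(X, X @ W, Xte, test_betas.mean(axis=1, keepdims=True))
        assert res_mean.raw[0] > res_reps.raw[0] + 0.05

    def test_snr_monotonicity(self):
        from vidbold.pipeline import encoding_snr_sweep

        out = encoding_snr_sweep(0)
        assert out["mean_correlations"] == sorted(out["mean_correlations"])


class TestNoiseNormalize:
    def _rmap(self, rho):
        rho = np.asarray(rho, dtype=float)
        return ReliabilityMap(sb=2 * rho / (1 + rho), rho=rho)

    def test_simple_division(self):
        res = EncodingResult(raw=np.array([0.3, 0.6]))
        out = noise_normalize(res, self._rmap([0.6, 0.6]))
        assert out.normalized[0] == pytest.approx(0.5)
        assert out.normalized[1] == pytest.approx(1.0)

    def test_nonpositive_reliability_excluded(self):
        res = EncodingResult(raw=np.array([0.3, 0.4]))
        out = noise_normalize(res, self._rmap([0.5, -0.1]))
        assert np.isnan(out.normalized[1])
        assert out.n_excluded == 1

    def test_full_model_approaches_ceiling(self, rng):
        # model explains all explainable variance; rep-noise variance 0.2x
        # signal keeps the single-rep/5-average ratio near 1
        n_stim, n_vox = 500, 40
        signal = rng.standard_normal((n_stim, n_vox))
        noise_sd = np.sqrt(0.2)
        reps = signal[:, None, :] + noise_sd * rng.standard_normal((n_stim, 10, n_vox))
        from vidbold.reliability import split_half_reliability

        rmap = split_half_reliability(reps)
        # the "model" predicts the true signal exactly
        corrs = []
        for r in range(10):
            a = reps[:, r] - reps[:, r].mean(0)
            s = signal - signal.mean(0)
            corrs.append(
                (a * s).sum(0) / np.sqrt((a**2).sum(0) * (s**2).sum(0))
            )
        raw = np.mean(corrs, axis=0)
        normalized = raw / rmap.rho
        assert abs(normalized.mean() - 1.0) < 0.1


class TestContrasts:
    def _results(self, rng, n_subjects, n_vox, shift=0.0, roi=None):
        a, b = [], []
        for _ in range(n_subjects):
            base = rng.standard_normal(n_vox) * 0.05
            da = base + 0.05 * rng.standard_normal(n_vox)
            db = base + 0.05 * rng.standard_normal(n_vox)
            if roi is not None:
                da = da.copy()
                da[roi] += shift
            a.append(EncodingResult(raw=da, normalized=da))
            b.append(EncodingResult(raw=db, normalized=db))
        return a, b

    def test_identical_results_nothing_significant(self, rng):
        a, _ = self._results(rng, 8, 100)
        rois = {"r1": np.arange(100) < 50, "r2": np.arange(100) >= 50}
        table = contrast_feature_sets(a, a, rois, n_comparisons=22)
        assert np.allclose(table["mean_diff"], 0.0)
        assert not table["significant"].any()

    def test_injected_difference_survives_bonferroni(self, rng):
        roi_mask = np.arange(100) < 50
        a, b = self._results(rng, 10, 100, shift=0.2, roi=roi_mask)
        rois = {"hot": roi_mask, "cold": ~roi_mask}
        table = contrast_feature_sets(a, b, rois, n_comparisons=22)
        assert table.set_index("roi").loc["hot", "significant"]
        assert not table.set_index("roi").loc["cold", "significant"]

    def test_fdr_correction_mode(self, rng):
        a, b = self._results(rng, 10, 60, shift=0.3, roi=np.arange(60) < 30)
        rois = {"hot": np.arange(60) < 30, "cold": np.arange(60) >= 30}
        table = contrast_feature_sets(a, b, rois, correction="fdr")
        assert table.set_index("roi").loc["hot", "significant"]

    def test_shuffle_average_and_ordered_advantage(self, rng):
        # temporal structure: betas driven by ordered features; shuffled
        # features lose alignment, so the ordered model predicts better
        X = rng.standard_normal((200, 10))
        Xte = rng.standard_normal((30, 10))
        W = rng.standard_normal((10, 50))
        betas = X @ W
        test_betas = (Xte @ W)[:, None, :] + 0.5 * rng.standard_normal((30, 10, 50))
        ordered = fit_encode_predict(X, betas, Xte, test_betas)
        shuffled = []
        for _ in range(10):
            perm = rng.permutation(200)
            shuffled.append(fit_encode_predict(X[perm], betas, Xte, test_betas))
        shuf = average_encoding_results(shuffled)
        assert np.nanmean(ordered.raw) > np.nanmean(shuf.raw) + 0.3
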