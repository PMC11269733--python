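"""Searchlight RDMs, metadata RDMs, RSA maps, noise ceilings, model tests."""

import numpy as np
import pytest
from scipy import stats

from vidbold import rsa
from vidbold.rsa import (
    RDM,
    DegenerateRDMError,
    metadata_rdm,
    noise_ceilings,
    roi_model_comparison,
    rsa_map,
    searchlight_rdms,
    sphere_offsets,
)
from vidbold.synthdata import generate_metadata_embeddings


def _rdm(values, ids=None):
    return RDM(values=values, metric="one_minus_pearson", condition_ids=ids)


class TestSearchlight:
    def test_radius_4_sphere_has_257_lattice_points(self):
        assert sphere_offsets(4).shape[0] == 257

    def test_identical_and_anticorrelated_patterns(self, rng):
        grid = (6, 6, 6)
        base = rng.standard_normal(216)
        patterns = np.stack([base, base, -base])
        rdms = searchlight_rdms(patterns, grid, radius=2)
        center = 108
        assert rdms[center, 0, 1] == pytest.approx(0.0, abs=1e-10)
        assert rdms[center, 0, 2] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(rdms[center], rdms[center].T)
        assert np.allclose(np.diagonal(rdms[center]), 0.0, atol=1e-12)

    def test_affine_stimulus_rescaling_invariance(self, rng):
        # correlation across voxels is invariant to positively rescaling and
        # shifting each stimulus pattern as a whole
        grid = (5, 5, 5)
        patterns = rng.standard_normal((6, 125))
        scale = rng.uniform(0.5, 2.0, 6)[:, None]
        shift = rng.standard_normal(6)[:, None]
        a = searchlight_rdms(patterns, grid, radius=2)
        b = searchlight_rdms(patterns * scale + shift, grid, radius=2)
        assert np.allclose(a, b, atol=1e-9)

    def test_degenerate_pattern_yields_nan_rdm(self, rng):
        grid = (5, 5, 5)
        patterns = rng.standard_normal((4, 125))
        patterns[2] = 7.0  # constant stimulus pattern
        rdms = searchlight_rdms(patterns, grid, radius=2)
        assert np.isnan(rdms).all()

    def test_radius_validation(self, rng):
        patterns = rng.standard_normal((4, 27))
        with pytest.raises(ValueError):
            searchlight_rdms(patterns, (3, 3, 3), radius=4)
        with pytest.raises(DegenerateRDMError):
            searchlight_rdms(patterns, (3, 3, 3), radius=0)


class TestMetadataRDM:
    def test_identical_annotations_and_videos(self):
        emb = generate_metadata_embeddings(3, annotator_noise_sd=0.0, seed=0)
        # duplicate video 0's latent into video 1
        for cat in emb.annotations:
            emb.annotations[cat][1] = [a.copy() for a in emb.annotations[cat][0]]
        rdm = metadata_rdm(emb, "scene")
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.metric == "cosine_distance"

    def test_orthogonal_vectors_distance_one(self):
        emb = generate_metadata_embeddings(2, annotator_noise_sd=0.0, seed=1)
        lat = np.zeros((2, 300))
        lat[0, 0] = lat[1, 1] = 1.0
        emb.annotations["action"] = [[lat[v][None, :]] * 5 for v in range(2)]
        rdm = metadata_rdm(emb, "action")
        assert rdm.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_combined_category_concatenates_to_900(self):
        emb = generate_metadata_embeddings(4, seed=2)
        vecs = rsa.category_vectors(emb, "object+scene+action")
        assert vecs.shape == (4, 900)

    def test_rdm_similarity_monotone_in_latent_correlation(self):
        corrs = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            emb = generate_metadata_embeddings(40, seed=5, cross_category_corr=rho)
            a = metadata_rdm(emb, "scene").vector()
            b = metadata_rdm(emb, "action").vector()
            corrs.append(stats.spearmanr(a, b).statistic)
        assert corrs == sorted(corrs)

    def test_fewer_than_three_annotations_rejected(self):
        emb = generate_metadata_embeddings(2, seed=3)
        emb.annotations["scene"][0] = emb.annotations["scene"][0][:2]
        with pytest.raises(ValueError, match="3 annotations"):
            metadata_rdm(emb, "scene")


class TestRSAMap:
    def test_model_equal_to_neural_gives_one(self, rng):
        d = np.abs(rng.standard_normal((8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        assert rsa_map(d[None], _rdm(d))[0] == pytest.approx(1.0, abs=1e-12)

    def test_permuted_model_near_zero(self, rng):
        n = 102
        vals = []
        neural = np.abs(rng.standard_normal((n, n)))
        neural = (neural + neural.T) / 2
        np.fill_diagonal(neural, 0)
        for _ in range(100):
            perm = rng.permutation(n)
            vals.append(rsa_map(neural[None], _rdm(neural[perm][:, perm]))[0])
        assert abs(np.mean(vals)) < 0.05

    def test_monotone_transform_invariance(self, rng):
        d = np.abs(rng.standard_normal((10, 10)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        neural = np.abs(rng.standard_normal((10, 10)))
        neural = (neural + neural.T) / 2
        np.fill_diagonal(neural, 0)
        a = rsa_map(neural[None], _rdm(d))
        b = rsa_map(neural[None], _rdm(np.exp(3 * d)))
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_constant_model_rejected(self, rng):
        neural = np.abs(rng.standard_normal((5, 5)))
        with pytest.raises(DegenerateRDMError):
            rsa_map(neural[None], _rdm(np.ones((5, 5))))


class TestNoiseCeilings:
    def test_identical_rdms_give_unit_ceilings(self, rng):
        d = np.abs(rng.standard_normal((1, 7, 7)))
        rdms = np.repeat(d[None], 5, axis=0)
        ceil = noise_ceilings(rdms)
        assert ceil.upper[0] == pytest.approx(1.0, abs=1e-12)
        assert ceil.lower[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_rdms_lower_unbiased_upper_self_inflated(self, rng):
        rdms = np.abs(rng.standard_normal((10, 1, 102, 102)))
        ceil = noise_ceilings(rdms)
        # leave-one-out ceiling is unbiased under independence; the upper
        # ceiling includes each subject in the group mean, giving the
        # analytic 1/sqrt(N) self-correlation
        assert abs(ceil.lower[0]) < 0.05
        assert ceil.upper[0] == pytest.approx(1 / np.sqrt(10), abs=0.06)

    def test_lower_below_upper_with_shared_signal(self, rng):
        count = 0
        for _ in range(200):
            shared = rng.standard_normal((12, 20))
            rdms = np.empty((6, 1, 12, 12))
            for s in range(6):
                pat = shared + rng.standard_normal(shared.shape)
                rdms[s, 0] = 1 - np.corrcoef(pat)
            ceil = noise_ceilings(rdms)
            count += int(ceil.lower[0] < ceil.upper[0])
        assert count >= 190  # >= 95% of replicates

    def test_subject_count_validation(self, rng):
        with pytest.raises(ValueError):
            noise_ceilings(np.abs(rng.standard_normal((2, 1, 5, 5))))


class TestModelComparison:
    def test_identical_models_nothing_flagged(self, rng):
        base = rng.standard_normal((8, 3, 1))
        values = np.repeat(base, 4, axis=2)
        table, pairwise = roi_model_comparison(values, ["r1", "r2", "r3"], list("abcd"))
        assert not table["significant"].any()
        assert pairwise == {}

    def test_shifted_model_significant_against_all(self, rng):
        values = rng.standard_normal((10, 1, 4)) * 0.1
        values[:, 0, 2] += 5.0
        table, pairwise = roi_model_comparison(values, ["roi"], list("abcd"), n_bonferroni=22)
        assert table["significant"].iloc[0]
        pairs = pairwise["roi"]
        involving_c = pairs[(pairs["model_a"] == "c") | (pairs["model_b"] == "c")]
        assert involving_c["significant"].all()

    def test_two_group_tukey_agrees_with_ttest(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12) + 2.0
        values = np.stack([a, b], axis=1)[:, None, :]
        _, pairwise = roi_model_comparison(values, ["roi"], ["a", "b"], n_bonferroni=1)
        p_tukey = pairwise["roi"]["p"].iloc[0]
        p_t = stats.ttest_ind(a, b).pvalue
        assert p_tukey == pytest.approx(p_t, abs=1e-6)
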