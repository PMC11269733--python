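"""Searchlight RDMs, metadata RDMs, RSA maps, noise ceilings, model
comparison.

Multivariate structure is summarized as representational dissimilarity
matrices (RDMs): for brain data, 1 - Pearson correlation between the
stimulus patterns inside a spherical searchlight (radius 4 voxels, 257
lattice points when fully interior); for metadata, cosine distance between
per-video annotation embeddings (the 3 most mutually similar of 5
annotations are averaged into the video's vector).  Model-to-brain
similarity is the Spearman correlation over lower-triangle RDM entries;
between-subject reliability bounds come from subject-to-group (upper) and
leave-one-out (lower) RDM correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


class DegenerateRDMError(ValueError):
    pass


@dataclass
class RDM:
    values: np.ndarray  # (n, n) symmetric, zero diagonal
    metric: str  # one_minus_pearson | cosine_distance
    condition_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        """Lower-triangle entries, diagonal excluded."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


@dataclass
class NoiseCeiling:
    upper: np.ndarray
    lower: np.ndarray


# ---------------------------------------------------------------------------
# Searchlight


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets with x^2 + y^2 + z^2 <= radius^2.

    Radius 4 gives 257 voxels."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def searchlight_rdms(
    patterns: np.ndarray,
    grid: tuple[int, int, int],
    radius: int = 4,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """1 - Pearson RDM of the in-sphere stimulus patterns at every voxel.

    ``patterns`` is (stimuli, voxels) — the z-scored, delay- and
    repetition-averaged summaries.  Spheres are truncated at volume edges.
    Voxels whose sphere contains a constant stimulus pattern yield NaN RDMs
    (excluded from group maps downstream).  Returns (n_centers, S, S).
    """
    S, V = patterns.shape
    if V != int(np.prod(grid)):
        raise ValueError("patterns do not match the voxel grid")
    if radius < 1:
        raise DegenerateRDMError("searchlight radius must be >= 1 voxel")
    if radius >= min(grid):
        raise ValueError(f"radius {radius} exceeds grid {grid}")
    offsets = sphere_offsets(radius)
    if centers is None:
        centers = np.arange(V)
    coords = np.column_stack(np.unravel_index(centers, grid))
    out = np.full((len(centers), S, S), np.nan)
    for ci, c in enumerate(coords):
        neigh = c[None, :] + offsets
        ok = np.all((neigh >= 0) & (neigh < np.array(grid)[None, :]), axis=1)
        flat = np.ravel_multi_index(tuple(neigh[ok].T), grid)
        pat = patterns[:, flat]
        sd = pat.std(axis=1)
        if np.any(sd == 0):
            continue  # degenerate pattern: leave NaN
        out[ci] = 1.0 - np.corrcoef(pat)
    return out


# ---------------------------------------------------------------------------
# Metadata RDMs


def _annotation_vector(entries: list[np.ndarray]) -> np.ndarray:
    """Average the most mutually similar 3 of (up to) 5 annotations.

    Each entry may hold several vectors from one annotator (multiple object
    labels); those are averaged first.  The triple with maximal mean
    pairwise cosine similarity, searched exhaustively over the C(5,3)
    triples, is averaged into the video's vector.
    """
    vecs = np.stack([np.atleast_2d(e).mean(axis=0) for e in entries[:5]])
    if vecs.shape[0] < 3:
        raise ValueError("at least 3 annotations per video are required")
    norm = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    sim = norm @ norm.T
    best, best_score = None, -np.inf
    for triple in combinations(range(vecs.shape[0]), 3):
        idx = list(triple)
        score = (sim[np.ix_(idx, idx)].sum() - 3.0) / 6.0  # mean of 3 off-diag pairs
        if score > best_score:
            best, best_score = idx, score
    return vecs[best].mean(axis=0)


def category_vectors(embeddings, category: str) -> np.ndarray:
    """Per-video consensus vectors for one metadata category."""
    if category == "object+scene+action":
        return np.hstack([category_vectors(embeddings, c) for c in ("object", "scene", "action")])
    per_video = embeddings.annotations[category]
    return np.stack([_annotation_vector(anns) for anns in per_video])


def metadata_rdm(embeddings, category: str, condition_ids=None) -> RDM:
    """Cosine-distance RDM between per-video consensus embeddings.

    ``category`` is object, scene, action, sentence, or the concatenated
    object+scene+action (vector length 900 at the default word dimension).
    """
    vecs = category_vectors(embeddings, category)
    d = squareform(pdist(vecs, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return RDM(values=d, metric="cosine_distance", condition_ids=condition_ids)


# ---------------------------------------------------------------------------
# RSA correlation maps


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def rsa_map(neural_rdms: np.ndarray, model_rdm: RDM) -> np.ndarray:
    """Spearman correlation of a model RDM with each voxel's neural RDM.

    Uses lower-triangle entries only (average ranks for ties).  Voxels with
    missing (NaN) neural RDMs return NaN.
    """
    n = model_rdm.n
    if neural_rdms.shape[-1] != n:
        raise ValueError("condition sets of neural and model RDMs do not match")
    i, j = np.tril_indices(n, k=-1)
    model_vec = model_rdm.values[i, j]
    if np.ptp(model_vec) == 0:
        raise DegenerateRDMError("constant model RDM: rank correlation undefined")
    neural_vecs = neural_rdms[..., i, j]
    flat = neural_vecs.reshape(-1, neural_vecs.shape[-1])
    out = np.full(flat.shape[0], np.nan)
    valid = ~np.isnan(flat).any(axis=1)
    if valid.any():
        mr = _rank(model_vec)
        mr = (mr - mr.mean()) / np.sqrt(np.sum((mr - mr.mean()) ** 2))
        nr = _rank(flat[valid], axis=1)
        nr = nr - nr.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.sum(nr**2, axis=1))
        ok = norms > 0
        vals = np.full(nr.shape[0], np.nan)
        vals[ok] = (nr[ok] / norms[ok, None]) @ mr
        out[valid] = vals
    return out.reshape(neural_vecs.shape[:-1])


def _spearman_vec(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.spearmanr(a, b).statistic)


def noise_ceilings(subject_rdms: np.ndarray) -> NoiseCeiling:
    """Upper/lower noise ceilings from per-subject searchlight RDMs.

    ``subject_rdms`` is (n_subjects, n_voxels, S, S).  Upper: mean over
    subjects of the Spearman correlation between each subject's RDM and the
    all-subject average RDM; lower: same against the average of the
    remaining subjects.
    """
    N = subject_rdms.shape[0]
    if N < 3:
        raise ValueError("at least 3 subjects required for noise ceilings")
    n_vox = subject_rdms.shape[1]
    n = subject_rdms.shape[-1]
    i, j = np.tril_indices(n, k=-1)
    vecs = subject_rdms[..., i, j]  # (N, V, P)
    mean_all = vecs.mean(axis=0)
    upper = np.zeros(n_vox)
    lower = np.zeros(n_vox)
    for v in range(n_vox):
        ups, lows = [], []
        for s in range(N):
            others = vecs[np.arange(N) != s, v].mean(axis=0)
            ups.append(_spearman_vec(vecs[s, v], mean_all[v]))
            lows.append(_spearman_vec(vecs[s, v], others))
        upper[v] = np.mean(ups)
        lower[v] = np.mean(lows)
    return NoiseCeiling(upper=upper, lower=lower)


# ---------------------------------------------------------------------------
# ROI-level model comparison


def roi_model_comparison(
    values: np.ndarray,
    roi_names: list[str],
    model_names: list[str],
    alpha: float = 0.05,
    n_bonferroni: int | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One-way ANOVA across models per ROI, Tukey HSD where significant.

    ``values`` is (n_subjects, n_rois, n_models) of noise-normalized
    correlations (each subject's correlations divided by their upper
    ceiling before entry).  ANOVA p-values are Bonferroni-corrected over
    ROIs; significant ROIs get a pairwise Tukey HSD table at FWER alpha.
    """
    n_subj, n_roi, n_model = values.shape
    if n_model < 2 or n_subj < 2:
        raise ValueError("need >= 2 models and >= 2 subjects")
    if n_bonferroni is None:
        n_bonferroni = n_roi
    rows, pairwise = [], {}
    for r, roi in enumerate(roi_names):
        groups = [values[:, r, m] for m in range(n_model)]
        if all(np.allclose(g, groups[0]) for g in groups[1:]):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
        p_corr = min(1.0, p * n_bonferroni)
        significant = p_corr < alpha
        rows.append(
            {"roi": roi, "F": f_stat, "p": p, "p_bonferroni": p_corr, "significant": significant}
        )
        if significant:
            res = stats.tukey_hsd(*groups)
            pairs = []
            for a in range(n_model):
                for b in range(a + 1, n_model):
                    pairs.append(
                        {
                            "model_a": model_names[a],
                            "model_b": model_names[b],
                            "diff": float(np.mean(groups[a]) - np.mean(groups[b])),
                            "p": float(res.pvalue[a, b]),
                            "significant": bool(res.pvalue[a, b] < alpha),
                        }
                    )
            pairwise[roi] = pd.DataFrame(pairs)
    return pd.DataFrame(rows), pairwise
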