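"""Voxelwise feature-to-brain encoding models.

Stimulus features (e.g. activations of a video network's blocks) are
standardized with training-set statistics, compressed to 100 principal
components fit on the training set, and mapped to each voxel's response
with ordinary least squares.  Predictions for held-out test videos are
Pearson-correlated with each of the 10 test repetitions and the 10
correlations averaged; dividing by the voxel's mean split-half correlation
(pre Spearman-Brown) gives the noise-normalized accuracy.  Feature-set
contrasts (early vs late block, unshuffled vs frame-shuffled input) are
per-ROI one-sample t-tests across subjects with the stated
multiple-comparison scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .gstats import bh_fdr
from .reliability import ReliabilityMap


class InsufficientRankError(ValueError):
    pass


@dataclass
class EncodingResult:
    raw: np.ndarray  # per-voxel mean correlation over test repetitions
    normalized: np.ndarray | None = None
    n_excluded: int = 0  # voxels with non-positive split-half correlation


def prepare_features(
    train: np.ndarray,
    test: np.ndarray,
    n_components: int = 100,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Train-fit standardization + PCA applied to train and test features.

    Component signs are fixed (largest-magnitude loading positive) so the
    transform is deterministic.  Raises when the training features cannot
    support ``n_components`` (too few stimuli or too low rank).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[1] != test.shape[1]:
        raise ValueError("train and test feature dimensionality differ")
    n_train, n_feat = train.shape
    if n_components > min(n_train - 1, n_feat):
        raise InsufficientRankError(
            f"{n_components} components not supported by {n_train} x {n_feat} features"
        )
    if standardize:
        mu = train.mean(axis=0)
        sd = train.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        train = (train - mu) / sd
        test = (test - mu) / sd
    rank = np.linalg.matrix_rank(train - train.mean(axis=0))
    if rank < n_components:
        raise InsufficientRankError(f"training features have rank {rank} < {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    train_pcs = pca.fit_transform(train)
    test_pcs = pca.transform(test)
    flip = np.sign(pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)])
    return train_pcs * flip, test_pcs * flip


def _ols_fit_predict(train_X: np.ndarray, train_Y: np.ndarray, test_X: np.ndarray) -> np.ndarray:
    Xtr = np.column_stack([np.ones(len(train_X)), train_X])
    Xte = np.column_stack([np.ones(len(test_X)), test_X])
    W, *_ = np.linalg.lstsq(Xtr, train_Y, rcond=None)
    return Xte @ W


def _columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching columns of two (n, V) arrays."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt(np.sum(a**2, axis=0) * np.sum(b**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, np.sum(a * b, axis=0) / denom, np.nan)


def fit_encode_predict(
    train_feats: np.ndarray,
    train_betas: np.ndarray,
    test_feats: np.ndarray,
    test_betas: np.ndarray,
    voxel_mask: np.ndarray | None = None,
) -> EncodingResult:
    """OLS encoding: fit on repetition-averaged training betas, evaluate
    against each test repetition and average the correlations.

    ``train_betas`` is (n_train, V); ``test_betas`` is (n_test, n_reps, V).
    With ``voxel_mask`` only the selected (reliable) voxels are predicted;
    other voxels report NaN.
    """
    V = train_betas.shape[1]
    if voxel_mask is None:
        voxel_mask = np.ones(V, dtype=bool)
    pred = _ols_fit_predict(train_feats, train_betas[:, voxel_mask], test_feats)
    n_reps = test_betas.shape[1]
    corrs = np.stack(
        [_columnwise_pearson(pred, test_betas[:, r, voxel_mask]) for r in range(n_reps)]
    )
    raw = np.full(V, np.nan)
    raw[voxel_mask] = corrs.mean(axis=0)
    return EncodingResult(raw=raw)


def noise_normalize(result: EncodingResult, reliability: ReliabilityMap) -> EncodingResult:
    """Divide raw correlations by the pre-correction split-half correlation.

    Voxels with non-positive split-half correlation are excluded (NaN) and
    counted.  Values can exceed 1 when the model beats the ceiling
    estimate; they are reported unclipped.
    """
    rho = reliability.rho
    ok = rho > 0
    normalized = np.where(ok, result.raw / np.where(ok, rho, 1.0), np.nan)
    return EncodingResult(
        raw=result.raw,
        normalized=normalized,
        n_excluded=int((~ok & ~np.isnan(result.raw)).sum()),
    )


def average_encoding_results(results: list[EncodingResult]) -> EncodingResult:
    """Mean across e.g. the ten frame-shuffle repetitions."""
    raw = np.nanmean([r.raw for r in results], axis=0)
    norms = [r.normalized for r in results]
    normalized = None if any(n is None for n in norms) else np.nanmean(norms, axis=0)
    return EncodingResult(raw=raw, normalized=normalized)


def contrast_feature_sets(
    results_a: list[EncodingResult],
    results_b: list[EncodingResult],
    roi_masks: dict[str, np.ndarray],
    correction: str = "bonferroni",
    n_comparisons: int | None = None,
    alpha: float = 0.05,
    use_normalized: bool = True,
) -> pd.DataFrame:
    """Per-ROI feature-set contrast (A - B) across subjects.

    ``results_a``/``results_b`` are per-subject results on identical voxel
    sets.  The ROI mean difference is tested against 0 with a one-sample
    two-sided t-test; ``correction`` is 'bonferroni' (over ``n_comparisons``,
    e.g. 22 ROIs) or 'fdr' (Benjamini-Hochberg over the supplied rows —
    concatenate the rows of all blocks first for the 88-comparison scheme).
    """
    if len(results_a) != len(results_b):
        raise ValueError("subject lists differ in length")
    rows = []
    for roi, mask in roi_masks.items():
        diffs = []
        for ra, rb in zip(results_a, results_b):
            a = ra.normalized if use_normalized else ra.raw
            b = rb.normalized if use_normalized else rb.raw
            d = a[mask] - b[mask]
            diffs.append(np.nanmean(d))
        diffs = np.asarray(diffs)
        if np.allclose(diffs, diffs[0]):
            t, p = (0.0, 1.0) if np.isclose(diffs[0], 0) else (np.inf * np.sign(diffs[0]), 0.0)
        else:
            t, p = stats.ttest_1samp(diffs, 0.0)
        rows.append({"roi": roi, "mean_diff": float(diffs.mean()), "t": float(t), "p": float(p)})
    table = pd.DataFrame(rows)
    m = n_comparisons if n_comparisons is not None else len(table)
    if correction == "bonferroni":
        table["significant"] = table["p"] * m < alpha
    elif correction == "fdr":
        table["significant"] = bh_fdr(table["p"].to_numpy(), q=alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    table["correction"] = correction
    return table
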