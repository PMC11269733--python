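"""Per-TR epoch encoding and unique-variance partitioning.

To test whether different timepoints of the sluggish BOLD response carry
snapshots of different moments of a video, features of the video's first
and third seconds are each mapped to the brain with a per-TR encoding
model, producing two synthetic test responses.  The variance of the
measured test response uniquely explained by each epoch at each TR is the
adjusted R^2 of the regression on both synthetic instances minus the
adjusted R^2 of the regression on the other instance alone.  The TR at
which each epoch's unique variance peaks should differ by about the epoch
lag (2 s); voxels with a peak difference of 1-3 TRs across subjects are
assessed with a binomial test under a uniform-peak null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gstats import bh_fdr, binomial_fraction_test, group_ttest
from .rsa import sphere_offsets

#: Fraction of ordered peak-TR pairs on a 9-TR grid with difference in
#: [1, 3] under an independent-uniform null: (8 + 7 + 6) / 81.
DEFAULT_P0 = 21.0 / 81.0


@dataclass
class UniqueVarianceCurve:
    unique_first: np.ndarray  # (voxels, 9)
    unique_third: np.ndarray  # (voxels, 9)

    def peaks(self) -> tuple[np.ndarray, np.ndarray]:
        """1-based peak TR per epoch; argmax ties resolve to the earliest TR."""
        return (
            np.argmax(self.unique_first, axis=1) + 1,
            np.argmax(self.unique_third, axis=1) + 1,
        )

    def peak_difference(self) -> np.ndarray:
        p1, p3 = self.peaks()
        return p3 - p1


def adjusted_r2(r2: float | np.ndarray, n: int, p: int):
    """1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _ols_predict(train_X: np.ndarray, train_Y: np.ndarray, test_X: np.ndarray) -> np.ndarray:
    Xtr = np.column_stack([np.ones(len(train_X)), train_X])
    Xte = np.column_stack([np.ones(len(test_X)), test_X])
    W, *_ = np.linalg.lstsq(Xtr, train_Y, rcond=None)
    return Xte @ W


def epoch_encode(
    epoch_train_feats: dict[int, np.ndarray],
    train_betas_per_tr: np.ndarray,
    epoch_test_feats: dict[int, np.ndarray],
) -> dict[int, np.ndarray]:
    """Synthetic test responses from each epoch's features, per TR.

    ``train_betas_per_tr`` is (n_train, 9, V), repetition-averaged but not
    delay-averaged.  At each TR a single OLS model with both epochs'
    feature sets entered jointly as predictors is fit on the training set;
    each epoch's learned weight block is then applied to that epoch's test
    features, giving one (n_test, 9, V) synthetic instance per epoch.
    Fitting jointly (rather than one epoch at a time) keeps each epoch's
    weights free of omitted-variable leakage from the other epoch.
    """
    epochs = sorted(epoch_train_feats)
    for e in epochs:
        if epoch_train_feats[e].shape[1] != epoch_test_feats[e].shape[1]:
            raise ValueError("train/test feature dimensionality differ")
    n_tr = train_betas_per_tr.shape[1]
    widths = [epoch_train_feats[e].shape[1] for e in epochs]
    train_X = np.column_stack(
        [np.ones(len(epoch_train_feats[epochs[0]]))] + [epoch_train_feats[e] for e in epochs]
    )
    out = {e: [] for e in epochs}
    bounds = np.cumsum([1] + widths)
    for t in range(n_tr):
        W, *_ = np.linalg.lstsq(train_X, train_betas_per_tr[:, t, :], rcond=None)
        for i, e in enumerate(epochs):
            block = W[bounds[i] : bounds[i + 1]]
            out[e].append(epoch_test_feats[e] @ block)
    return {e: np.stack(v, axis=1) for e, v in out.items()}


def _adj_r2_multi(y: np.ndarray, preds: list[np.ndarray]) -> float:
    """Adjusted R^2 of OLS of y on the given predictors (plus intercept)."""
    n = y.size
    p = len(preds)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    X = np.column_stack([np.ones(n)] + preds)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
    return adjusted_r2(r2, n, p)


def unique_variance_direct(bio: np.ndarray, synth_a: np.ndarray, synth_b: np.ndarray):
    """Unique adjusted-R^2 of each predictor for one observation vector.

    unique(A) = adjR^2(bio ~ A + B) - adjR^2(bio ~ B), and symmetrically
    for B.  Inputs are flat observation vectors.
    """
    full = _adj_r2_multi(bio, [synth_a, synth_b])
    only_a = _adj_r2_multi(bio, [synth_a])
    only_b = _adj_r2_multi(bio, [synth_b])
    return full - only_b, full - only_a, full


def _sphere_sum(per_voxel: np.ndarray, grid, radius: int) -> np.ndarray:
    """Sum a per-voxel quantity over the (edge-truncated) searchlight sphere."""
    from scipy import ndimage

    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    kernel = (dx**2 + dy**2 + dz**2 <= r**2).astype(float)
    out = ndimage.convolve(per_voxel.reshape(grid), kernel, mode="constant", cval=0.0)
    return out.ravel()


def unique_variance(
    bio: np.ndarray,
    synth_first: np.ndarray,
    synth_third: np.ndarray,
    grid: tuple[int, int, int],
    radius: int = 4,
    mode: str = "stacked",
    demean: bool = True,
) -> UniqueVarianceCurve:
    """Searchlight unique-variance curves over TRs 1..9.

    All inputs are (n_videos, 9, V) with ``bio`` the measured test response
    averaged over its repetitions.  In 'stacked' mode the regression's
    observations at a center voxel are the (videos x in-sphere voxels)
    values; in 'center' mode only the center voxel's videos.  With
    ``demean`` (default) every voxel's mean across videos is removed per TR
    before stacking, so the shared stimulus-evoked baseline — which varies
    across voxels but not videos and which a single pooled intercept cannot
    absorb — does not masquerade as unexplained variance.

    Implemented with sphere-summed cross-moments, algebraically identical
    to running the nested OLS fits at every (center, TR).
    """
    n_videos, n_tr, V = bio.shape
    if synth_first.shape != bio.shape or synth_third.shape != bio.shape:
        raise ValueError("bio and synthetic instances must share (video, TR, voxel) grids")
    if V != int(np.prod(grid)):
        raise ValueError("voxel count does not match grid")
    if mode not in ("stacked", "center"):
        raise ValueError(f"unknown mode {mode!r}")

    y, a, b = bio, synth_first, synth_third
    if demean:
        y = y - y.mean(axis=0, keepdims=True)
        a = a - a.mean(axis=0, keepdims=True)
        b = b - b.mean(axis=0, keepdims=True)

    # per-(TR, voxel) sums over videos
    sums = {"y": y.sum(0), "a": a.sum(0), "b": b.sum(0)}
    prods = {
        "yy": (y * y).sum(0), "aa": (a * a).sum(0), "bb": (b * b).sum(0),
        "ya": (y * a).sum(0), "yb": (y * b).sum(0), "ab": (a * b).sum(0),
    }
    if mode == "stacked":
        counts = _sphere_sum(np.ones(V), grid, radius)
        sums = {k: np.stack([_sphere_sum(v[t], grid, radius) for t in range(n_tr)], 1) for k, v in sums.items()}
        prods = {k: np.stack([_sphere_sum(v[t], grid, radius) for t in range(n_tr)], 1) for k, v in prods.items()}
    else:
        counts = np.ones(V)
        sums = {k: v.T for k, v in sums.items()}
        prods = {k: v.T for k, v in prods.items()}
    n = (n_videos * counts)[:, None]  # (V, 1)
    if np.min(n) <= 3:
        raise ValueError("need more than p + 1 = 3 observations per regression")

    def C(xy, x, y_):
        return prods[xy] - sums[x] * sums[y_] / n

    cyy, caa, cbb = C("yy", "y", "y"), C("aa", "a", "a"), C("bb", "b", "b")
    cya, cyb, cab = C("ya", "y", "a"), C("yb", "y", "b"), C("ab", "a", "b")

    with np.errstate(divide="ignore", invalid="ignore"):
        r2_a = np.where((caa > 0) & (cyy > 0), cya**2 / (caa * cyy), 0.0)
        r2_b = np.where((cbb > 0) & (cyy > 0), cyb**2 / (cbb * cyy), 0.0)
        det = caa * cbb - cab**2
        good = det > 1e-12 * np.maximum(caa * cbb, 1e-300)
        beta_a = np.where(good, (cbb * cya - cab * cyb) / np.where(good, det, 1.0), 0.0)
        beta_b = np.where(good, (caa * cyb - cab * cya) / np.where(good, det, 1.0), 0.0)
        explained = beta_a * cya + beta_b * cyb
        r2_full = np.where(good & (cyy > 0), explained / cyy, np.maximum(r2_a, r2_b))

    adj_full = 1.0 - (1.0 - r2_full) * (n - 1) / (n - 3)  # p = 2
    adj_a = 1.0 - (1.0 - r2_a) * (n - 1) / (n - 2)  # p = 1
    adj_b = 1.0 - (1.0 - r2_b) * (n - 1) / (n - 2)
    return UniqueVarianceCurve(unique_first=adj_full - adj_b, unique_third=adj_full - adj_a)


def peak_tr_analysis(
    peak_diffs: np.ndarray,
    p0: float = DEFAULT_P0,
    diff_range: tuple[int, int] = (1, 3),
    q: float = 0.05,
) -> pd.DataFrame:
    """Whole-brain binomial test on the per-voxel count of subjects whose
    peak-TR difference falls in ``diff_range``, FDR-corrected.

    ``peak_diffs`` is (n_subjects, V).  Returns a per-voxel table with the
    subject count, binomial p, FDR flag and percent of subjects in range.
    """
    n_subj, V = peak_diffs.shape
    lo, hi = diff_range
    in_range = (peak_diffs >= lo) & (peak_diffs <= hi)
    k = in_range.sum(axis=0)
    p_cache = {kk: binomial_fraction_test(int(kk), n_subj, p0, side="greater").p for kk in np.unique(k)}
    pvals = np.array([p_cache[kk] for kk in k])
    reject = bh_fdr(pvals, q=q)
    return pd.DataFrame(
        {
            "voxel": np.arange(V),
            "n_in_range": k,
            "p": pvals,
            "significant": reject,
            "pct_subjects": 100.0 * k / n_subj,
        }
    )


def roi_peak_table(
    curves_per_subject: list[UniqueVarianceCurve],
    roi_masks: dict[str, np.ndarray],
    alpha: float = 0.05,
    n_tr_comparisons: int = 18,
) -> pd.DataFrame:
    """Per-ROI peak differences and per-TR unique-variance significance.

    The ROI curve per subject is the mean unique variance over ROI voxels;
    peak difference is tested across subjects with a two-sided one-sample
    t-test, and each epoch's per-TR unique variance with one-sided tests
    FDR-corrected over 9 TRs x 2 epochs comparisons.
    """
    rows = []
    for roi, mask in roi_masks.items():
        first = np.stack([c.unique_first[mask].mean(axis=0) for c in curves_per_subject])
        third = np.stack([c.unique_third[mask].mean(axis=0) for c in curves_per_subject])
        diffs = (np.argmax(third, axis=1) + 1) - (np.argmax(first, axis=1) + 1)
        t_res = group_ttest(diffs.astype(float), 0.0, sides="two", alpha=alpha)
        per_tr_p = []
        for curve in (first, third):
            for t in range(curve.shape[1]):
                per_tr_p.append(group_ttest(curve[:, t], 0.0, sides="greater").p)
        per_tr_sig = bh_fdr(np.asarray(per_tr_p)[:n_tr_comparisons], q=alpha)
        rows.append(
            {
                "roi": roi,
                "mean_peak_diff": float(diffs.mean()),
                "t": t_res.statistic,
                "p": t_res.p,
                "significant": t_res.significant,
                "n_tr_significant": int(per_tr_sig.sum()),
            }
        )
    return pd.DataFrame(rows)
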