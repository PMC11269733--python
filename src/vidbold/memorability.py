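"""Memorability decay model and neural memorability correlations.

A video's memorability score m_T is its recognition probability referenced
to a lag of T = 80 intervening videos; the linear decay model
m_t = m_T + alpha (t - T) predicts memorability at any lag t.  The neural
analysis ranks-correlates (Spearman) the per-video memorability scores
with each voxel's response amplitude (betas z-scored across stimuli,
averaged over the peak delay window and over repetitions, training and
testing sets pooled) and tests the correlation across subjects one-sided
toward positive values, the a-priori direction of memorability effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gstats import bh_fdr, bonferroni

REFERENCE_LAG = 80.0


@dataclass
class MemorabilityRecord:
    score: float  # m_T in [0, 1]
    decay: float  # alpha; typically negative, positives preserved
    reference_lag: float = REFERENCE_LAG

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("memorability score must lie in [0, 1]")


def memorability_at_lag(record: MemorabilityRecord, t: float) -> float:
    """m_t = m_T + alpha (t - T), clipped to [0, 1]."""
    if t < 0:
        raise ValueError("lag must be non-negative")
    return float(np.clip(record.score + record.decay * (t - record.reference_lag), 0.0, 1.0))


def clip_decay(decay: np.ndarray) -> np.ndarray:
    """Optionally clip positive decay rates to 0 (off by default upstream)."""
    return np.minimum(decay, 0.0)


def _spearman_columns(scores: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Spearman correlation of scores with each column of betas."""
    sr = stats.rankdata(scores)
    br = stats.rankdata(betas, axis=0)
    sr = sr - sr.mean()
    br = br - br.mean(axis=0)
    denom = np.sqrt(np.sum(sr**2) * np.sum(br**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, sr @ br / denom, np.nan)


def memorability_correlation(
    scores: np.ndarray,
    betas_per_subject: list[np.ndarray],
    q: float = 0.05,
    roi_masks: dict[str, np.ndarray] | None = None,
    n_bonferroni: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Voxelwise memorability correlations with group-level inference.

    ``betas_per_subject`` holds (n_videos, V) repetition- and delay-averaged
    z-scored responses; ``scores`` the matching per-video memorability.
    Whole brain: one-sample one-sided (positive) t-test across subjects per
    voxel, BH-FDR at ``q``.  ROI: per-subject mean correlation per ROI,
    one-sided t-test, Bonferroni over the ROI count.
    """
    scores = np.asarray(scores, dtype=float)
    corr = []
    for betas in betas_per_subject:
        if betas.shape[0] != scores.size:
            raise ValueError("scores and betas disagree on the number of videos")
        corr.append(_spearman_columns(scores, betas))
    corr = np.stack(corr)  # (n_subjects, V)

    t_res = stats.ttest_1samp(corr, 0.0, axis=0, alternative="greater")
    pvals = np.asarray(t_res.pvalue)
    significant = bh_fdr(pvals, q=q)

    out = {
        "correlations": corr,
        "group_p": pvals,
        "significant": significant,
        "mean_correlation": corr.mean(axis=0),
    }
    if roi_masks is not None:
        m = n_bonferroni if n_bonferroni is not None else len(roi_masks)
        rows = []
        for roi, mask in roi_masks.items():
            per_subj = np.array([np.nanmean(c[mask]) for c in corr])
            res = stats.ttest_1samp(per_subj, 0.0, alternative="greater")
            rows.append(
                {
                    "roi": roi,
                    "mean_corr": float(per_subj.mean()),
                    "t": float(res.statistic),
                    "p": float(res.pvalue),
                    "significant": bool(bonferroni(np.array([res.pvalue]), alpha=alpha, m=m)[0]),
                }
            )
        out["roi_table"] = pd.DataFrame(rows)
    return out
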