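"""Univariate split-half reliability with Spearman-Brown correction.

Voxels are selected by a split-half criterion on the 10-repetition testing
set: the ten repetitions are divided into the 126 unordered complementary
5/5 partitions, the two 5-repetition averages are Pearson-correlated across
stimuli, each split correlation rho passes through the Spearman-Brown
formula SB = 2 rho / (1 + rho), and the mean over partitions is the voxel's
reliability.  Chance level is estimated by re-pairing stimuli: one split's
stimulus labels are permuted (one fresh permutation per iteration, applied
to all partitions in that iteration) and the mean SB recomputed; the
permutation p-value uses the add-one rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np


@dataclass
class ReliabilityMap:
    sb: np.ndarray  # mean Spearman-Brown reliability per voxel
    rho: np.ndarray  # mean split correlation per voxel (pre-correction)
    p: np.ndarray | None = None  # permutation p-value
    reliable: np.ndarray | None = None


def spearman_brown(rho):
    """SB = 2 rho / (1 + rho); fixes 0 and 1, strictly increasing on (-1, 1]."""
    rho = np.asarray(rho, dtype=float)
    return 2.0 * rho / (1.0 + rho)


def split_half_partitions(n_reps: int = 10) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """The C(10,5)/2 = 126 unordered complementary half partitions."""
    all_reps = set(range(n_reps))
    parts = []
    for half in combinations(range(n_reps), n_reps // 2):
        if 0 in half:  # keep one representative of each complementary pair
            parts.append((half, tuple(sorted(all_reps - set(half)))))
    return parts


def _standardize(x: np.ndarray) -> np.ndarray:
    """Center across stimuli and scale to unit sum of squares, per voxel."""
    x = x - x.mean(axis=0, keepdims=True)
    norm = np.sqrt(np.sum(x**2, axis=0, keepdims=True))
    return np.divide(x, norm, out=np.zeros_like(x), where=norm > 0)


def _split_means(betas: np.ndarray):
    """Standardized 5-repetition averages for each of the 126 partitions."""
    parts = split_half_partitions(betas.shape[1])
    A = np.stack([_standardize(betas[:, p1].mean(axis=1)) for p1, _ in parts])
    B = np.stack([_standardize(betas[:, p2].mean(axis=1)) for _, p2 in parts])
    return A, B


def _check_input(betas: np.ndarray) -> None:
    if betas.ndim != 3:
        raise ValueError("betas must be (stimuli, repetitions, voxels)")
    if betas.shape[1] != 10:
        raise ValueError(f"exactly 10 repetitions required, got {betas.shape[1]}")
    if betas.shape[0] < 3:
        raise ValueError("at least 3 stimuli required")


def split_half_reliability(betas: np.ndarray) -> ReliabilityMap:
    """Mean Spearman-Brown reliability over all 126 five/five partitions.

    ``betas`` is (stimuli, 10 repetitions, voxels), already delay-averaged
    and z-scored.  Negative split correlations pass through the formula
    unmodified.
    """
    _check_input(betas)
    A, B = _split_means(betas)
    rho = np.einsum("psv,psv->pv", A, B)
    return ReliabilityMap(sb=spearman_brown(rho).mean(axis=0), rho=rho.mean(axis=0))


def permutation_null(
    betas: np.ndarray, n_perm: int = 100, seed: int | None = None
) -> ReliabilityMap:
    """Permutation p-values for the split-half reliability criterion.

    p = (#{null >= observed} + 1) / (n_perm + 1), so the smallest attainable
    p with 100 permutations is 1/101 and an observation below every null
    gives exactly 1.0.
    """
    _check_input(betas)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    A, B = _split_means(betas)
    rho_obs = np.einsum("psv,psv->pv", A, B)
    observed = spearman_brown(rho_obs).mean(axis=0)

    n_stim = betas.shape[0]
    exceed = np.zeros(observed.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n_stim)
        rho_null = np.einsum("psv,psv->pv", A[:, perm], B)
        null_sb = spearman_brown(rho_null).mean(axis=0)
        exceed += null_sb >= observed
    p = (exceed + 1.0) / (n_perm + 1.0)
    return ReliabilityMap(sb=observed, rho=rho_obs.mean(axis=0), p=p)


def select_reliable_voxels(rmap: ReliabilityMap, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of voxels whose permutation p-value is below alpha."""
    if rmap.p is None:
        raise ValueError("permutation p-values not computed")
    mask = rmap.p < alpha
    rmap.reliable = mask
    return mask


def roi_reliability_table(rmap: ReliabilityMap, roi_masks: dict[str, np.ndarray]):
    """Per-ROI counts of reliable voxels and their mean reliability."""
    import pandas as pd

    rows = []
    for name, mask in roi_masks.items():
        sel = mask & (rmap.reliable if rmap.reliable is not None else np.ones_like(mask))
        rows.append(
            {
                "roi": name,
                "n_voxels": int(mask.sum()),
                "n_reliable": int(sel.sum()),
                "mean_sb": float(rmap.sb[sel].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
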