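"""ROI definition from localizer contrasts with probabilistic-map overlap
resolution.

Per-subject t-contrast maps are thresholded at a family-wise error level
(Bonferroni over in-mask voxels), binarized and averaged across subjects
into a probabilistic map; a subject's ROI is their surviving voxels within
the map's support, capped at the top 1000 by t-value.  Voxels claimed by
several ROIs go to the ROI with the higher probability at that voxel; ties
are broken by growing a cube one voxel per dimension at a time and
comparing mean probabilities inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class ProbMap:
    """Fraction of subjects significant at each voxel (grid-valued)."""

    values: np.ndarray  # 3-D, entries on the 1/n_subjects grid

    @property
    def grid(self):
        return self.values.shape


@dataclass
class ROIMask:
    name: str
    mask: np.ndarray  # 3-D boolean

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def build_probabilistic_map(
    tmaps: np.ndarray, df: int, fwe_alpha: float = 0.05, in_mask: np.ndarray | None = None
) -> ProbMap:
    """Binarize each subject's t-map at the Bonferroni FWE threshold, average.

    ``tmaps`` is (n_subjects, X, Y, Z).  The comparison count is the number
    of in-mask voxels (whole grid when no mask is given).
    """
    from scipy import stats

    tmaps = np.asarray(tmaps)
    if tmaps.ndim != 4 or tmaps.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, X, Y, Z) t-maps")
    if in_mask is None:
        in_mask = np.ones(tmaps.shape[1:], dtype=bool)
    if in_mask.shape != tmaps.shape[1:]:
        raise ValueError("mask shape does not match t-maps")
    m = int(in_mask.sum())
    thresh = stats.t.ppf(1.0 - fwe_alpha / m, df)
    binarized = (tmaps > thresh) & in_mask[None]
    return ProbMap(values=binarized.mean(axis=0))


def define_roi(
    subject_tmap: np.ndarray,
    probmap: ProbMap,
    anatomical_mask: np.ndarray,
    df: int,
    name: str = "roi",
    top_k: int = 1000,
    fwe_alpha: float = 0.05,
) -> ROIMask:
    """Subject ROI: FWE-surviving voxels in probmap support and anatomy,
    capped at the ``top_k`` largest t-values.  An empty result is returned
    as an empty mask with a warning (some subjects lack certain regions)."""
    from scipy import stats

    if subject_tmap.shape != probmap.values.shape:
        raise ValueError("t-map and probability map are not aligned")
    m = int(anatomical_mask.sum()) or subject_tmap.size
    thresh = stats.t.ppf(1.0 - fwe_alpha / m, df)
    surviving = (subject_tmap > thresh) & (probmap.values > 0) & anatomical_mask
    if not surviving.any():
        warnings.warn(f"ROI {name!r} is empty for this subject", RuntimeWarning)
        return ROIMask(name=name, mask=surviving)
    if surviving.sum() > top_k:
        t_vals = np.where(surviving, subject_tmap, -np.inf)
        cutoff_idx = np.argsort(t_vals.ravel())[::-1][:top_k]
        mask = np.zeros(subject_tmap.size, dtype=bool)
        mask[cutoff_idx] = True
        surviving = mask.reshape(subject_tmap.shape)
    return ROIMask(name=name, mask=surviving)


def _patch_mean(values: np.ndarray, voxel: tuple[int, int, int], radius: int) -> float:
    sl = tuple(
        slice(max(0, c - radius), min(n, c + radius + 1))
        for c, n in zip(voxel, values.shape)
    )
    return float(values[sl].mean())


def resolve_overlaps(
    rois: list[ROIMask], probmaps: list[ProbMap]
) -> list[ROIMask]:
    """Assign each multiply-claimed voxel to a single ROI.

    Primary rule: the ROI whose probabilistic map is larger at that voxel.
    Ties: compare the mean probability inside a cube grown by one voxel per
    dimension per iteration until the tie breaks; if the cube spans the
    whole grid and the tie persists, the voxel goes to the first ROI with
    a warning (deterministic fallback).
    """
    if len(rois) != len(probmaps):
        raise ValueError("rois and probmaps must be given in the same order")
    grid = rois[0].mask.shape
    claims = np.sum([r.mask for r in rois], axis=0)
    resolved = [r.mask.copy() for r in rois]
    max_radius = max(grid)
    for voxel in zip(*np.nonzero(claims > 1)):
        claimants = [i for i, r in enumerate(rois) if r.mask[voxel]]
        probs = np.array([probmaps[i].values[voxel] for i in claimants])
        best = np.flatnonzero(probs == probs.max())
        radius = 1
        while len(best) > 1 and radius <= max_radius:
            means = np.array(
                [_patch_mean(probmaps[claimants[b]].values, voxel, radius) for b in best]
            )
            best = best[np.flatnonzero(means == means.max())]
            radius += 1
        if len(best) > 1:
            warnings.warn(
                f"unresolvable probability tie at voxel {voxel}; assigned to "
                f"{rois[claimants[best[0]]].name!r}",
                RuntimeWarning,
            )
        winner = claimants[best[0]]
        for i in claimants:
            if i != winner:
                resolved[i][voxel] = False
    return [ROIMask(name=r.name, mask=m) for r, m in zip(rois, resolved)]


def regrid_mask_nearest(mask: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour regridding of an (atlas) mask onto another grid."""
    zoom = [t / s for t, s in zip(target_shape, mask.shape)]
    return ndimage.zoom(mask.astype(np.uint8), zoom, order=0).astype(bool)
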