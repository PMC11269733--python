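"""Temporal resampling and FIR / canonical-HRF general linear modeling.

The acquisition TR (1.75 s) is incommensurate with the 4 s trial length, so
each voxel's time series is first resampled to a 1 s grid with cubic
interpolation; trial onsets then fall on integer volumes and the BOLD
response can be modeled time-locked to video onset with finite impulse
response (FIR) regressors at delays 1..9 s.  Each (trial, delay) pair gets
its own indicator column; null trials are not modeled.  The fit projects
out a discrete-cosine high-pass set (cutoff 1/128 Hz) from data and design
and optionally prewhitens with a pooled AR(1) coefficient estimated from
the residuals.

Because consecutive trials are only 4 s apart while the FIR window is 9 s
long, indicator columns of neighboring trials can land on the same
timepoint, which makes the trial-wise design rank-deficient by
construction.  The fit therefore uses minimum-norm least squares; the
resulting betas split a shared timepoint's signal equally among the trials
covering it, which downstream z-scoring and repetition averaging treat as
additional trial noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .design import RunSchedule
from .synthdata import VolumeSeries, double_gamma_hrf

N_DELAYS = 9


class MisalignedOnsetError(ValueError):
    """Trial onset does not fall on the (resampled) volume grid."""


class RankDeficientDesignError(ValueError):
    pass


class AR1ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Temporal resampling


def resample_timeseries(series: VolumeSeries, tr_out: float = 1.0) -> VolumeSeries:
    """Cubic-interpolate a run's series onto a ``tr_out`` grid from run start.

    The output covers 0..floor(last acquired time) seconds, i.e. length
    floor((T-1) * tr_in / tr_out) + 1 samples, never extrapolating.
    """
    data = series.data
    T = data.shape[0]
    if T < 4:
        raise ValueError("cubic interpolation needs at least 4 timepoints")
    t_in = np.arange(T) * series.tr_s
    n_out = int(np.floor(t_in[-1] / tr_out + 1e-9)) + 1
    t_out = np.arange(n_out) * tr_out
    resampled = CubicSpline(t_in, data, axis=0)(t_out)
    return VolumeSeries(
        data=resampled,
        tr_s=tr_out,
        grid=series.grid,
        run_type=series.run_type,
        run_index=series.run_index,
        session_index=series.session_index,
    )


# ---------------------------------------------------------------------------
# FIR design


@dataclass(frozen=True)
class FIRColumn:
    trial_index: int
    condition_id: str
    repetition_index: int
    delay: int  # seconds post-onset, 1..9
    truncated: bool


@dataclass
class FIRDesign:
    matrix: np.ndarray  # (timepoints, columns)
    columns: list[FIRColumn] = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


def build_fir_design(
    schedule: RunSchedule,
    n_timepoints: int,
    tr_s: float = 1.0,
    n_delays: int = N_DELAYS,
) -> FIRDesign:
    """One indicator column per (stimulus trial, delay 1..n_delays).

    Columns whose single timepoint would fall past the end of the run are
    kept but flagged ``truncated`` (their column is all zero and their beta
    is reported as missing).
    """
    cols = []
    labels = []
    for j, e in enumerate(schedule.events):
        if e.is_null:
            continue
        onset_vol = e.onset_s / tr_s
        if abs(onset_vol - round(onset_vol)) > 1e-6:
            raise MisalignedOnsetError(
                f"onset {e.onset_s} s is not aligned to the {tr_s} s grid"
            )
        onset_vol = int(round(onset_vol))
        for d in range(1, n_delays + 1):
            row = onset_vol + d
            col = np.zeros(n_timepoints)
            truncated = row >= n_timepoints
            if not truncated:
                col[row] = 1.0
            cols.append(col)
            labels.append(
                FIRColumn(
                    trial_index=j,
                    condition_id=e.condition_id,
                    repetition_index=e.repetition_index,
                    delay=d,
                    truncated=truncated,
                )
            )
    matrix = np.column_stack(cols) if cols else np.zeros((n_timepoints, 0))
    return FIRDesign(matrix=matrix, columns=labels)


# ---------------------------------------------------------------------------
# High-pass filtering


def dct_highpass_basis(n_timepoints: int, tr_s: float = 1.0, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine set spanning fluctuations slower than ``cutoff_s``.

    Includes the constant term; the number of cosine components is
    floor(2 * T * tr / cutoff), the usual convention for fMRI high-pass
    filtering.
    """
    T = n_timepoints
    k_max = int(np.floor(2.0 * T * tr_s / cutoff_s))
    t = np.arange(T)
    cols = [np.ones(T) / np.sqrt(T)]
    for k in range(1, k_max + 1):
        c = np.cos(np.pi * k * (2 * t + 1) / (2 * T))
        cols.append(c / np.linalg.norm(c))
    return np.column_stack(cols)


def highpass_project(arr: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residualize columns of ``arr`` against the (orthonormal) cosine set."""
    return arr - basis @ (basis.T @ arr)


# ---------------------------------------------------------------------------
# FIR fit


@dataclass
class FIRFit:
    betas: np.ndarray  # (columns, voxels); NaN for truncated columns
    columns: list[FIRColumn]
    ar1_phi: float | None
    rank: int


def _pooled_ar1(resid: np.ndarray) -> float:
    num = float(np.sum(resid[1:] * resid[:-1]))
    den = float(np.sum(resid[:-1] ** 2))
    return num / den if den > 0 else 0.0


def fit_fir_glm(
    series: VolumeSeries,
    design: FIRDesign,
    highpass_cutoff_s: float = 128.0,
    ar1: bool = True,
    require_full_rank: bool = False,
) -> FIRFit:
    """Least-squares FIR betas after high-pass filtering, optional AR(1).

    The cosine set is projected out of both data and design.  With ``ar1``
    a single AR(1) coefficient pooled over voxels is estimated from the
    first-pass residuals, data and design are prewhitened, and the model is
    refit.  Minimum-norm least squares handles the rank deficiency inherent
    to overlapping trial-wise FIR columns; set ``require_full_rank`` to
    instead raise on a deficient design.
    """
    Y = series.data
    X = design.matrix
    B = dct_highpass_basis(Y.shape[0], series.tr_s, highpass_cutoff_s)
    Xf = highpass_project(X, B)
    Yf = highpass_project(Y, B)

    beta, _, rank, _ = np.linalg.lstsq(Xf, Yf, rcond=None)
    if require_full_rank and rank < X.shape[1]:
        raise RankDeficientDesignError(
            f"design rank {rank} < {X.shape[1]} columns"
        )
    phi = None
    if ar1:
        resid = Yf - Xf @ beta
        phi = _pooled_ar1(resid)
        if abs(phi) >= 1.0:
            raise AR1ConvergenceError(f"estimated AR(1) coefficient {phi} out of range")
        Xw = Xf.copy()
        Yw = Yf.copy()
        Xw[1:] -= phi * Xf[:-1]
        Yw[1:] -= phi * Yf[:-1]
        s0 = np.sqrt(1.0 - phi**2)
        Xw[0] *= s0
        Yw[0] *= s0
        beta, _, rank, _ = np.linalg.lstsq(Xw, Yw, rcond=None)

    truncated = np.array([c.truncated for c in design.columns])
    if truncated.any():
        beta[truncated] = np.nan
    return FIRFit(betas=beta, columns=design.columns, ar1_phi=phi, rank=int(rank))


# ---------------------------------------------------------------------------
# Beta tensor


@dataclass
class BetaTensor:
    """FIR betas indexed (stimulus, repetition, delay 1..9, voxel)."""

    values: np.ndarray
    stimulus_ids: list[str]
    delays: np.ndarray = field(default_factory=lambda: np.arange(1, N_DELAYS + 1))


def collect_beta_tensor(
    fits: list[FIRFit],
    stimulus_ids: list[str],
    n_reps: int,
    n_delays: int = N_DELAYS,
) -> BetaTensor:
    """Assemble per-run FIR fits into a (stimulus, rep, delay, voxel) tensor.

    Repetition indices come from the schedule (1-based, global across
    sessions).  Entries never estimated (truncated columns) remain NaN.
    """
    n_vox = fits[0].betas.shape[1]
    index = {s: i for i, s in enumerate(stimulus_ids)}
    values = np.full((len(stimulus_ids), n_reps, n_delays, n_vox), np.nan)
    for fit in fits:
        for row, col in zip(fit.betas, fit.columns):
            s = index.get(col.condition_id)
            if s is None:
                continue
            values[s, col.repetition_index - 1, col.delay - 1] = row
    return BetaTensor(values=values, stimulus_ids=list(stimulus_ids))


def summarize_betas(
    tensor: BetaTensor,
    delay_window: tuple[int, int] = (5, 9),
    zscore: bool = True,
    average_reps: bool = True,
) -> np.ndarray:
    """Z-score across stimuli, average over a delay window and repetitions.

    Z-scoring happens per (repetition, delay, voxel) across stimuli before
    any averaging.  Zero-variance voxels map to 0 (with a warning).  Returns
    (stimuli, voxels) or, with ``average_reps=False``, (stimuli, reps,
    voxels).
    """
    lo, hi = delay_window
    delays = tensor.delays
    if lo < delays[0] or hi > delays[-1] or lo > hi:
        raise ValueError(f"delay window {delay_window} outside {delays[0]}..{delays[-1]}")
    vals = tensor.values
    if zscore:
        mu = np.nanmean(vals, axis=0, keepdims=True)
        sd = np.nanstd(vals, axis=0, keepdims=True)
        degenerate = sd == 0
        if degenerate.any():
            warnings.warn("zero-variance voxels z-scored to 0", RuntimeWarning)
        sd = np.where(degenerate, 1.0, sd)
        vals = np.where(np.broadcast_to(degenerate, vals.shape), 0.0, (vals - mu) / sd)
    sel = (delays >= lo) & (delays <= hi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(vals[:, :, sel], axis=2)
        if average_reps:
            out = np.nanmean(out, axis=1)
    return out


# ---------------------------------------------------------------------------
# Localizer (block design, canonical HRF)


class UnknownContrastError(KeyError):
    pass


def fit_localizer_glm(
    series: VolumeSeries,
    block_events: list[tuple[float, float, str]],
    contrasts: dict[str, dict[str, float]],
    dt: float = 0.1,
) -> dict[str, np.ndarray]:
    """Canonical-HRF block GLM returning one t-map per contrast.

    ``block_events`` are (onset_s, duration_s, condition) triples; baseline
    periods are left unmodeled.  Contrasts are mappings from condition name
    to weight, e.g. {"faces": 1, "objects": -1}.
    """
    Y = series.data
    T = Y.shape[0]
    conditions = sorted({c for *_, c in block_events})
    duration = T * series.tr_s
    n_fine = int(np.ceil(duration / dt)) + 1
    kernel = double_gamma_hrf(np.arange(0, 32 + dt, dt))
    regs = []
    for cond in conditions:
        box = np.zeros(n_fine)
        for onset, dur, c in block_events:
            if c == cond:
                box[int(round(onset / dt)) : int(round((onset + dur) / dt))] = 1.0
        conv = np.convolve(box, kernel)[:n_fine]
        t_idx = np.round(np.arange(T) * series.tr_s / dt).astype(int)
        regs.append(conv[t_idx])
    X = np.column_stack(regs + [np.ones(T)])
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = T - np.linalg.matrix_rank(X)
    sigma2 = np.sum(resid**2, axis=0) / df
    xtx_inv = pinv @ pinv.T

    out = {}
    for name, weights in contrasts.items():
        c = np.zeros(X.shape[1])
        for cond, w in weights.items():
            if cond not in conditions:
                raise UnknownContrastError(f"unknown condition {cond!r} in contrast {name!r}")
            c[conditions.index(cond)] = w
        var = float(c @ xtx_inv @ c)
        t = (c @ beta) / np.sqrt(sigma2 * var)
        out[name] = t
    out["_df"] = np.array(df)
    return out


def localizer_t_threshold(df: int, alpha: float, n_comparisons: int) -> float:
    """One-sided Bonferroni (FWE) t threshold across in-mask voxels."""
    return float(stats.t.ppf(1.0 - alpha / n_comparisons, df))
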