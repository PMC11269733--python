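"""Synthetic BOLD data, feature, embedding and memorability generators.

The generator emulates the statistics of the study design with a known
ground truth so every downstream stage (FIR GLM, reliability, encoding,
variance partitioning, RSA, memorability) has a recoverable target:

* each stimulus trial adds a double-gamma-HRF-convolved response whose
  amplitude at a voxel is driven by a first-second latent at video onset and
  a third-second latent two seconds later (the temporal-epoch lag),
* the whole trial response is scaled by ``1 + memorability_effect * score``,
* measurement noise is AR(1) in time, plus slow cosine drift that the GLM's
  discrete-cosine high-pass set removes by construction.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .design import RunSchedule, SessionSchedule, build_session_schedule


class GridTooSmallError(ValueError):
    """Voxel grid cannot host the requested searchlight radius."""


# ---------------------------------------------------------------------------
# Hemodynamic response


def double_gamma_hrf(t, peak_s: float = 5.0, undershoot_s: float = 15.0, ratio: float = 6.0):
    """Canonical double-gamma HRF, peak normalized to 1.

    Gamma shapes are chosen so the positive lobe peaks at ``peak_s`` and the
    undershoot at ``undershoot_s`` (unit scale: a gamma pdf with shape a has
    its mode at a - 1).
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_s + 1.0) - stats.gamma.pdf(t, undershoot_s + 1.0) / ratio
    h = np.where(t < 0, 0.0, h)
    fine = np.arange(0, 32, 0.01)
    hmax = np.max(stats.gamma.pdf(fine, peak_s + 1.0) - stats.gamma.pdf(fine, undershoot_s + 1.0) / ratio)
    return h / hmax


# ---------------------------------------------------------------------------
# Configuration and ground truth


@dataclass
class SynthConfig:
    """Desk-scale default configuration.

    Counts scale linearly with the full-scale design (1000/102 videos,
    10 subjects, whole-brain grids); the defaults keep the same trial,
    repetition and session structure at a size suited to exhaustive testing.
    """

    n_subjects: int = 4
    n_train_videos: int = 60
    n_test_videos: int = 12
    train_reps: int = 3
    test_reps: int = 10
    n_sessions: int = 2
    train_runs_per_session: int = 3
    test_runs_per_session: int = 2
    grid: tuple[int, int, int] = (16, 16, 16)
    n_latent: int = 10
    signal_sd: float = 1.0
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    epoch_lag_s: float = 2.0
    baseline_amplitude: float = 6.0
    reliable_fraction: float = 0.3
    memorability_effect: float = 4.0
    memorability_effect_fraction: float = 0.2
    drift_sd: float = 1.0
    n_drift: int = 3
    highpass_cutoff_s: float = 128.0
    acq_tr_s: float = 1.75
    mem_mean: float = 0.8422
    mem_sd: float = 0.0888
    decay_mean: float = -0.0014
    decay_sd: float = 0.0011

    @property
    def n_videos(self) -> int:
        return self.n_train_videos + self.n_test_videos

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid))


@dataclass
class GroundTruth:
    """Latents, weights and nuisance parameters behind a synthetic dataset."""

    video_ids: list[str]
    latent_features: dict[int, np.ndarray]  # epoch (1, 3) -> (n_videos, k)
    voxel_weights: np.ndarray  # (k, n_voxels)
    reliable_voxel_mask: np.ndarray  # (n_voxels,) bool
    memorability_effect: np.ndarray  # (n_voxels,)
    memorability_scores: np.ndarray  # (n_videos,)
    memorability_decay: np.ndarray  # (n_videos,)
    signal_sd: float
    noise_sd: float
    ar1_phi: float
    epoch_lag_s: float
    baseline_amplitude: float

    def __post_init__(self):
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("|ar1_phi| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        scores = np.asarray(self.memorability_scores)
        if scores.size and (scores.min() < 0 or scores.max() > 1):
            raise ValueError("memorability scores must lie in [0, 1]")


@dataclass
class VolumeSeries:
    """One run's voxel time series (timepoints x voxels) on a 3-D grid."""

    data: np.ndarray
    tr_s: float
    grid: tuple[int, int, int]
    run_type: str = ""
    run_index: int = 0
    session_index: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume series contains non-finite values")


def make_ground_truth(config: SynthConfig, seed: int) -> GroundTruth:
    rng = np.random.default_rng(seed)
    V = config.n_voxels
    k = config.n_latent
    video_ids = [f"train_{i:04d}" for i in range(config.n_train_videos)] + [
        f"test_{i:03d}" for i in range(config.n_test_videos)
    ]
    latents = {
        1: rng.standard_normal((config.n_videos, k)),
        3: rng.standard_normal((config.n_videos, k)),
    }
    n_rel = int(round(config.reliable_fraction * V))
    reliable = np.zeros(V, dtype=bool)
    reliable[rng.choice(V, size=n_rel, replace=False)] = True
    weights = np.zeros((k, V))
    w = rng.standard_normal((k, n_rel))
    # unit-norm weight columns: every reliable voxel has stimulus-driven
    # amplitude SD exactly signal_sd (per epoch)
    weights[:, reliable] = config.signal_sd * w / np.linalg.norm(w, axis=0, keepdims=True)

    n_eff = int(round(config.memorability_effect_fraction * V))
    n_eff = min(n_eff, n_rel)
    effect = np.zeros(V)
    rel_idx = np.flatnonzero(reliable)
    effect[rng.choice(rel_idx, size=n_eff, replace=False)] = config.memorability_effect

    scores, decay = generate_memorability(
        config.n_videos,
        mean=config.mem_mean,
        sd=config.mem_sd,
        seed=int(rng.integers(2**31 - 1)),
        decay_mean=config.decay_mean,
        decay_sd=config.decay_sd,
    )
    return GroundTruth(
        video_ids=video_ids,
        latent_features=latents,
        voxel_weights=weights,
        reliable_voxel_mask=reliable,
        memorability_effect=effect,
        memorability_scores=scores,
        memorability_decay=decay,
        signal_sd=config.signal_sd,
        noise_sd=config.noise_sd,
        ar1_phi=config.ar1_phi,
        epoch_lag_s=config.epoch_lag_s,
        baseline_amplitude=config.baseline_amplitude,
    )


def resample_voxel_weights(truth: GroundTruth, config: SynthConfig, seed: int) -> GroundTruth:
    """A per-subject variant of the ground truth: same stimuli, scores,
    reliable-voxel and memorability-effect masks, freshly drawn voxel
    tuning.  Subjects share where signal lives but not its fine-grained
    pattern, so chance stimulus-sampling correlations do not replicate
    across subjects."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    k, V = truth.voxel_weights.shape
    reliable = truth.reliable_voxel_mask
    weights = np.zeros((k, V))
    w = rng.standard_normal((k, int(reliable.sum())))
    weights[:, reliable] = config.signal_sd * w / np.linalg.norm(w, axis=0, keepdims=True)
    return replace(truth, voxel_weights=weights)


def trial_amplitudes(truth: GroundTruth, epoch: int) -> np.ndarray:
    """Per-(video, voxel) trial response amplitude for one temporal epoch.

    Half of the baseline response is attributed to each epoch; the video's
    latent projects through the voxel weights, and the memorability score
    scales the whole response multiplicatively.  The baseline term is the
    mean evoked visual response, several times larger than the
    stimulus-specific modulation; it is what makes a multiplicative
    memorability gain visible as a positive score-response correlation.
    """
    base = 0.5 * truth.baseline_amplitude * truth.reliable_voxel_mask.astype(float)
    amp = base[None, :] + truth.latent_features[epoch] @ truth.voxel_weights
    gain = 1.0 + truth.memorability_effect[None, :] * truth.memorability_scores[:, None]
    return amp * gain


def ar1_noise(shape, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal SD ``sd``."""
    T = shape[0]
    out = np.empty(shape)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    out[0] = rng.standard_normal(shape[1:]) * sd
    eps = rng.standard_normal(shape) * innov_sd
    for t in range(1, T):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _drift(duration_s: float, times: np.ndarray, config: SynthConfig, rng: np.random.Generator, n_voxels: int):
    """Slow cosine drift restricted to the GLM's own high-pass band.

    The number of components is capped at the size of the discrete-cosine
    set the GLM will project out, so the high-pass removes the drift by
    construction.
    """
    T_res = int(np.floor(duration_s)) + 1  # resampled (1 s) length
    k_max = int(np.floor(2.0 * T_res / config.highpass_cutoff_s))
    n = min(config.n_drift, k_max)
    if n < 1:
        return np.zeros((times.size, n_voxels))
    amps = rng.standard_normal((n, n_voxels)) * config.drift_sd
    basis = np.stack(
        [np.cos(np.pi * k * (2 * times + 1) / (2 * T_res)) for k in range(1, n + 1)]
    )
    return basis.T @ amps


def generate_run(
    schedule: RunSchedule,
    truth: GroundTruth,
    config: SynthConfig,
    rng: np.random.Generator,
    session_index: int = 0,
    dt: float = 0.25,
) -> VolumeSeries:
    """Simulate one run's BOLD series at the acquisition TR."""
    video_index = {vid: i for i, vid in enumerate(truth.video_ids)}
    V = truth.voxel_weights.shape[1]
    duration = schedule.n_volumes * schedule.tr_s
    T_fine = int(np.ceil(duration / dt)) + 1
    impulses = np.zeros((T_fine, V))
    amp1 = trial_amplitudes(truth, 1)
    amp3 = trial_amplitudes(truth, 3)
    for e in schedule.stimulus_events():
        v = video_index[e.condition_id]
        i1 = int(round(e.onset_s / dt))
        i3 = int(round((e.onset_s + truth.epoch_lag_s) / dt))
        impulses[i1] += amp1[v]
        if i3 < T_fine:
            impulses[i3] += amp3[v]
    kernel = double_gamma_hrf(np.arange(0, 32 + dt, dt))
    clean_fine = sp_signal.fftconvolve(impulses, kernel[:, None], axes=0)[:T_fine]

    step = schedule.tr_s / dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError("acquisition TR must be a multiple of the simulation dt")
    idx = (np.arange(schedule.n_volumes) * int(round(step)))
    data = clean_fine[idx]
    times = np.arange(schedule.n_volumes) * schedule.tr_s
    if truth.noise_sd > 0:
        data = data + ar1_noise(data.shape, truth.ar1_phi, truth.noise_sd, rng)
    data = data + _drift(duration, times, config, rng, V)
    return VolumeSeries(
        data=data,
        tr_s=schedule.tr_s,
        grid=config.grid,
        run_type=schedule.run_type,
        run_index=schedule.run_index,
        session_index=session_index,
    )


def generate_dataset(
    schedules: list[SessionSchedule],
    truth: GroundTruth,
    config: SynthConfig,
    seed: int | None,
    searchlight_radius: int = 4,
) -> dict[tuple[int, int], VolumeSeries]:
    """Simulate all runs of one participant, keyed by (session, run)."""
    if seed is None:
        raise ValueError("a seed is required: all randomness must be seeded")
    if min(config.grid) <= searchlight_radius:
        raise GridTooSmallError(
            f"grid {config.grid} cannot host searchlight radius {searchlight_radius}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sess in schedules:
        for run in sess.runs:
            out[(sess.session_index, run.run_index)] = generate_run(
                run, truth, config, rng, session_index=sess.session_index
            )
    return out


def build_subject_schedules(config: SynthConfig, seed: int) -> list[SessionSchedule]:
    return build_session_schedule(
        config.n_train_videos,
        config.n_test_videos,
        config.train_reps,
        config.test_reps,
        config.n_sessions,
        seed,
        train_runs_per_session=config.train_runs_per_session,
        test_runs_per_session=config.test_runs_per_session,
        tr_s=config.acq_tr_s,
    )


# ---------------------------------------------------------------------------
# Beta-level shortcut

def generate_beta_dataset(
    truth: GroundTruth,
    video_indices: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    beta_noise_sd: float = 1.0,
    n_delays: int = 9,
) -> np.ndarray:
    """Per-repetition FIR-like betas drawn directly from the ground truth.

    Returns (n_videos, n_reps, n_delays, n_voxels): the epoch-1 amplitude
    traced through the HRF at delays 1..9 plus the epoch-3 amplitude at a
    lag of ``epoch_lag_s``, with i.i.d. estimation noise per repetition.
    Used by the larger multi-subject experiments where the interest is in
    group inference over betas rather than the deconvolution itself.
    """
    delays = np.arange(1, n_delays + 1, dtype=float)
    h1 = double_gamma_hrf(delays)
    h3 = double_gamma_hrf(delays - truth.epoch_lag_s)
    amp1 = trial_amplitudes(truth, 1)[video_indices]
    amp3 = trial_amplitudes(truth, 3)[video_indices]
    clean = amp1[:, None, :] * h1[None, :, None] + amp3[:, None, :] * h3[None, :, None]
    noise = rng.standard_normal((len(video_indices), n_reps, n_delays, amp1.shape[1]))
    return clean[:, None] + beta_noise_sd * noise


# ---------------------------------------------------------------------------
# Metadata embeddings


@dataclass
class EmbeddingSet:
    """Per-video annotation embeddings for each metadata category.

    ``annotations[category][video]`` is a list of per-annotator entries; each
    entry is a 2-D array (n_vectors x dim) whose rows are averaged before
    use (multiple rows emulate the several object labels one annotator may
    give; zero-row entries are not produced — a 'no more objects' choice
    simply reduces the row count).
    """

    annotations: dict[str, list[list[np.ndarray]]]
    dims: dict[str, int]
    latents: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_videos(self) -> int:
        return len(next(iter(self.annotations.values())))


WORD_CATEGORIES = ("object", "scene", "action")


def generate_metadata_embeddings(
    n_videos: int,
    dims: dict[str, int] | None = None,
    annotator_noise_sd: float = 0.3,
    seed: int | None = None,
    n_annotations: int = 5,
    cross_category_corr: float = 0.0,
) -> EmbeddingSet:
    """Emulated annotation embeddings: true latent vector + annotator noise.

    Word-level categories (object/scene/action) get 300-dim latents and the
    sentence category 384-dim.  ``cross_category_corr`` mixes a shared core
    into every category's latent to control how correlated the category RDMs
    are.  Object annotators contribute 1-3 vectors each.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if dims is None:
        dims = {"word": 300, "sentence": 384}
    rng = np.random.default_rng(seed)
    rho = float(cross_category_corr)
    core = rng.standard_normal((n_videos, 50))
    categories = {c: dims["word"] for c in WORD_CATEGORIES}
    categories["sentence"] = dims["sentence"]

    annotations: dict[str, list[list[np.ndarray]]] = {}
    latents: dict[str, np.ndarray] = {}
    for cat, d in categories.items():
        proj = rng.standard_normal((50, d)) / np.sqrt(50)
        shared = core @ proj
        own = rng.standard_normal((n_videos, d))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        latents[cat] = latent
        per_video = []
        for v in range(n_videos):
            anns = []
            for _ in range(n_annotations):
                n_vec = int(rng.integers(1, 4)) if cat == "object" else 1
                vecs = latent[v][None, :] + annotator_noise_sd * rng.standard_normal((n_vec, d))
                anns.append(vecs)
            per_video.append(anns)
        annotations[cat] = per_video
    return EmbeddingSet(annotations=annotations, dims=dims, latents=latents)


# ---------------------------------------------------------------------------
# Memorability


def generate_memorability(
    n_videos: int,
    mean: float = 0.8422,
    sd: float = 0.0888,
    seed: int | None = None,
    decay_mean: float = -0.0014,
    decay_sd: float = 0.0011,
) -> tuple[np.ndarray, np.ndarray]:
    """Memorability scores (clipped to [0, 1]) and decay rates.

    Defaults reproduce the behavioral summary statistics of the stimulus
    set: scores 0.8422 +/- 0.0888, decay -0.0014 +/- 0.0011.  Positive decay
    draws are preserved (they can be clipped downstream if desired).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean score must lie in (0, 1)")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    scores = np.clip(rng.normal(mean, sd, size=n_videos), 0.0, 1.0)
    decay = rng.normal(decay_mean, decay_sd, size=n_videos)
    return scores, decay
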