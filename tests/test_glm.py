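"""Temporal resampling, FIR design construction and GLM estimation."""

import numpy as np
import pytest

from vidbold import glm
from vidbold.design import RunSchedule, TrialEvent
from vidbold.glm import (
    MisalignedOnsetError,
    build_fir_design,
    collect_beta_tensor,
    dct_highpass_basis,
    fit_fir_glm,
    fit_localizer_glm,
    highpass_project,
    resample_timeseries,
    summarize_betas,
)
from vidbold.synthdata import VolumeSeries, double_gamma_hrf


def _series(data, tr=1.75):
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    return VolumeSeries(data=data, tr_s=tr, grid=(1, 1, data.shape[1]))


def _run(events, n_volumes, tr=1.0, lead_out=8.0):
    return RunSchedule(
        run_type="test", events=events, lead_in_s=4.0, lead_out_s=lead_out,
        tr_s=tr, n_volumes=n_volumes,
    )


def _event(onset, cond="test_000", rep=1):
    return TrialEvent(onset_s=onset, duration_s=4.0, condition_id=cond, repetition_index=rep)


class TestResampling:
    def test_constant_and_linear_are_exact(self):
        t_in = np.arange(40) * 1.75
        const = resample_timeseries(_series(np.full(40, 3.5)))
        assert np.allclose(const.data, 3.5)
        ramp = resample_timeseries(_series(2.0 * t_in + 1.0))
        t_out = np.arange(ramp.data.shape[0])
        assert np.allclose(ramp.data[:, 0], 2.0 * t_out + 1.0, atol=1e-9)

    def test_sinusoid_within_tolerance(self):
        t_in = np.arange(120) * 1.75
        out = resample_timeseries(_series(np.sin(2 * np.pi * t_in / 32)))
        t_out = np.arange(out.data.shape[0])
        interior = slice(2, -2)  # spline edges are less accurate
        assert np.max(np.abs(out.data[interior, 0] - np.sin(2 * np.pi * t_out[interior] / 32))) < 1e-3

    def test_output_grid_and_minimum_length(self):
        out = resample_timeseries(_series(np.zeros(40)))
        assert out.tr_s == 1.0
        assert out.data.shape[0] == int(np.floor(39 * 1.75)) + 1
        with pytest.raises(ValueError):
            resample_timeseries(_series(np.zeros(3)))


class TestFIRDesign:
    def test_single_trial_indicator_rows(self):
        design = build_fir_design(_run([_event(4.0)], 20), n_timepoints=20)
        assert design.matrix.shape == (20, 9)
        rows = [int(np.flatnonzero(col)[0]) for col in design.matrix.T]
        assert rows == list(range(5, 14))
        assert all(col.sum() == 1 for col in design.matrix.T)

    def test_overlapping_trials_share_sampled_rows(self):
        # Two trials 4 s apart cover timepoints 5..17: columns of the later
        # trial at delay d coincide with the earlier trial at delay d+4, so
        # the rank equals the number of distinct covered timepoints (13).
        events = [_event(4.0, rep=1), _event(8.0, "test_001", rep=1)]
        design = build_fir_design(_run(events, 24), n_timepoints=24)
        assert design.matrix.shape[1] == 18
        assert np.linalg.matrix_rank(design.matrix) == 13

    def test_trial_at_run_end_flagged_truncated(self):
        design = build_fir_design(_run([_event(4.0)], 10), n_timepoints=10)
        truncated = [c for c in design.columns if c.truncated]
        assert len(truncated) == 4  # delays 6..9 fall past the run end
        assert len(design.columns) == 9  # kept, not dropped

    def test_misaligned_onset_raises(self):
        with pytest.raises(MisalignedOnsetError):
            build_fir_design(_run([_event(4.3)], 30), n_timepoints=30)

    def test_null_trials_excluded(self):
        events = [
            _event(4.0),
            TrialEvent(8.0, 4.0, None, 0),
            _event(12.0, "test_001"),
        ]
        design = build_fir_design(_run(events, 30), n_timepoints=30)
        assert len({c.condition_id for c in design.columns}) == 2


class TestHighpass:
    def test_projection_idempotent_and_orthogonal(self, rng):
        basis = dct_highpass_basis(200)
        y = rng.standard_normal((200, 4))
        once = highpass_project(y, basis)
        twice = highpass_project(once, basis)
        assert np.allclose(once, twice, atol=1e-10)
        assert np.max(np.abs(basis.T @ once)) < 1e-8


class TestFIRFit:
    def _noiseless_run(self, amps, spacing=16.0, n_voxels=3):
        """Widely spaced trials with responses confined to delays 1..9:
        overlap-free and fully FIR-representable, so OLS recovery is exact."""
        events = [_event(4.0 + i * spacing, f"test_{i:03d}") for i in range(len(amps))]
        T = int(4 + len(amps) * spacing + 16)
        h = double_gamma_hrf(np.arange(1, 10.0))
        data = np.zeros((T, n_voxels))
        for e, a in zip(events, amps):
            onset = int(e.onset_s)
            data[onset + 1 : onset + 10] += a * h[:, None]
        series = VolumeSeries(data=data, tr_s=1.0, grid=(1, 1, n_voxels))
        return series, _run(events, T)

    def test_noiseless_recovery_matches_injected_profile(self):
        amps = [2.0, -1.0, 0.5]
        series, run = self._noiseless_run(amps)
        design = build_fir_design(run, series.data.shape[0])
        fit = fit_fir_glm(series, design, ar1=True)
        h = double_gamma_hrf(np.arange(1, 10.0))
        for col, beta in zip(fit.columns, fit.betas):
            expected = amps[col.trial_index] * h[col.delay - 1]
            assert np.max(np.abs(beta - expected)) < 1e-6

    def test_pure_slow_drift_filtered_to_zero(self):
        T = 300
        basis = dct_highpass_basis(T, cutoff_s=128.0)
        drift = 5.0 * basis[:, 1:4].sum(axis=1)  # inside the high-pass band
        series = _series(drift, tr=1.0)
        design = build_fir_design(_run([_event(4.0), _event(40.0, "test_001")], T), T)
        fit = fit_fir_glm(series, design, ar1=False)
        assert np.max(np.abs(fit.betas)) < 1e-6

    def test_white_noise_betas_unbiased(self, rng):
        T = 120
        design = build_fir_design(_run([_event(4.0), _event(30.0, "test_001")], T), T)
        betas = []
        for _ in range(200):
            series = _series(rng.standard_normal(T), tr=1.0)
            betas.append(fit_fir_glm(series, design, ar1=False).betas[:, 0])
        betas = np.array(betas)
        se = betas.std(axis=0) / np.sqrt(len(betas))
        assert np.all(np.abs(betas.mean(axis=0)) < 2.5 * se + 1e-12)

    def test_require_full_rank_raises_on_overlap(self):
        events = [_event(4.0), _event(8.0, "test_001")]
        T = 30
        design = build_fir_design(_run(events, T), T)
        series = _series(np.zeros(T), tr=1.0)
        with pytest.raises(glm.RankDeficientDesignError):
            fit_fir_glm(series, design, require_full_rank=True)


class TestSummarize:
    def _tensor(self, values):
        return glm.BetaTensor(values=values, stimulus_ids=[f"s{i}" for i in range(values.shape[0])])

    def test_known_tensor_mean_over_window_and_reps(self, rng):
        values = rng.standard_normal((5, 3, 9, 2))
        out = summarize_betas(self._tensor(values), zscore=False)
        expected = values[:, :, 4:9].mean(axis=(1, 2))
        assert np.allclose(out, expected, atol=1e-12)

    def test_zero_variance_voxels_map_to_zero(self):
        values = np.ones((4, 2, 9, 1))
        with pytest.warns(RuntimeWarning):
            out = summarize_betas(self._tensor(values), zscore=True)
        assert np.allclose(out, 0.0)

    def test_zscore_then_average_shrinks_sd(self, rng):
        values = rng.standard_normal((400, 10, 9, 1))
        out = summarize_betas(self._tensor(values), delay_window=(5, 5), zscore=True)
        # averaging 10 z-scored independent repetitions: SD ~ 1/sqrt(10)
        assert abs(out.std() - 1 / np.sqrt(10)) < 0.03

    def test_commutes_with_stimulus_permutation(self, rng):
        values = rng.standard_normal((6, 3, 9, 4))
        perm = rng.permutation(6)
        direct = summarize_betas(self._tensor(values))[perm]
        permuted = summarize_betas(self._tensor(values[perm]))
        assert np.allclose(direct, permuted, atol=1e-12)

    def test_window_validation(self, rng):
        values = rng.standard_normal((3, 2, 9, 1))
        with pytest.raises(ValueError):
            summarize_betas(self._tensor(values), delay_window=(5, 12))


class TestCollect:
    def test_tensor_assembly_and_truncation_nan(self):
        run = _run([_event(4.0, "test_000", rep=2)], 10)
        design = build_fir_design(run, 10)
        series = _series(np.ones(10), tr=1.0)
        fit = fit_fir_glm(series, design, ar1=False)
        tensor = collect_beta_tensor([fit], ["test_000"], n_reps=3)
        assert tensor.values.shape == (1, 3, 9, 1)
        assert np.isnan(tensor.values[0, 2, 0, 0])  # repetition 3 never seen
        assert np.isnan(tensor.values[0, 1, 8, 0])  # truncated delay
        assert np.isfinite(tensor.values[0, 1, 0, 0])


class TestLocalizer:
    def _block_series(self, amp_map, n_voxels, seed, noise=1.0, n_blocks=10):
        rng = np.random.default_rng(seed)
        events = []
        t = 10.0
        conditions = ["faces", "objects", "scenes"]
        for i in range(n_blocks):
            for c in conditions:
                events.append((t, 18.0, c))
                t += 18.0
            t += 18.0
        T = int(np.ceil((t + 10) / 1.75))
        dt = 0.25
        n_fine = int(np.ceil(T * 1.75 / dt)) + 1
        impulse = np.zeros((n_fine, n_voxels))
        for onset, dur, c in events:
            a = amp_map.get(c)
            if a is not None:
                impulse[int(onset / dt) : int((onset + dur) / dt)] += a * dt
        kernel = double_gamma_hrf(np.arange(0, 32 + dt, dt))
        from scipy.signal import fftconvolve

        clean = fftconvolve(impulse, kernel[:, None], axes=0)[:n_fine]
        idx = np.round(np.arange(T) * 1.75 / dt).astype(int)
        data = clean[idx] + noise * rng.standard_normal((T, n_voxels))
        return VolumeSeries(data=data, tr_s=1.75, grid=(1, 1, n_voxels)), events

    def test_selective_voxel_contrast(self):
        amp = np.zeros(2)
        series, events = self._block_series({"faces": np.array([3.0, 0.0])}, 2, seed=0)
        tmaps = fit_localizer_glm(
            series, events,
            {"faces>objects": {"faces": 1, "objects": -1}, "scenes>objects": {"scenes": 1, "objects": -1}},
        )
        assert tmaps["faces>objects"][0] > 5.0
        assert abs(tmaps["scenes>objects"][0]) < 3.0

    def test_null_calibration_five_percent(self):
        series, events = self._block_series({}, 1000, seed=1)
        tmaps = fit_localizer_glm(series, events, {"c": {"faces": 1, "objects": -1}})
        from scipy import stats

        crit = stats.t.ppf(0.975, int(tmaps["_df"]))
        frac = np.mean(np.abs(tmaps["c"]) > crit)
        assert abs(frac - 0.05) < 0.02

    def test_contrast_sign_negation(self):
        series, events = self._block_series({"faces": np.array([2.0])}, 1, seed=2)
        tmaps = fit_localizer_glm(
            series, events,
            {"f>o": {"faces": 1, "objects": -1}, "o>f": {"faces": -1, "objects": 1}},
        )
        assert tmaps["f>o"][0] == pytest.approx(-tmaps["o>f"][0], abs=1e-10)

    def test_unknown_contrast_condition_raises(self):
        series, events = self._block_series({}, 1, seed=3)
        with pytest.raises(glm.UnknownContrastError):
            fit_localizer_glm(series, events, {"bad": {"nonexistent": 1}})
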