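"""Filtering, dF/F0, trial extraction, control sampling, PCA denoising."""

import numpy as np
import pytest
from scipy import stats

from premove import (Session, EventTable, SynthConfig, bandpass_filter,
                     compute_dff, concat_sessions, extract_trials,
                     generate_session, lowpass_filter, pca_denoise,
                     sample_control_triggers)
from premove.exceptions import (DegenerateDataError, InsufficientDataError,
                                ParameterError)
from premove.preprocess import causal_shift_samples

FPS = 30.0


class TestFilters:
    def test_causal_delay_correction_is_100_steps(self):
        assert causal_shift_samples(0.3, 30.0) == 100

    def test_constant_passes_unchanged(self):
        x = np.full(3000, 2.5)
        for mode in ("zero_phase", "causal"):
            y = lowpass_filter(x, 0.3, FPS, mode=mode)
            np.testing.assert_allclose(y, x, atol=1e-8)

    def test_causal_aligned_with_zero_phase(self):
        """After the delay correction, causal output peaks align with the
        zero-phase output (peak cross-correlation lag 0 +- 1 sample)."""
        t = np.arange(0, 300, 1 / FPS)
        x = np.sin(2 * np.pi * 0.1 * t)
        zp = lowpass_filter(x, 0.3, FPS, mode="zero_phase")
        ca = lowpass_filter(x, 0.3, FPS, mode="causal")
        # interior only: the causal tail is padded
        a, b = zp[500:-500], ca[500:-500]
        xc = np.correlate(a - a.mean(), b - b.mean(), "full")
        lag = int(np.argmax(xc)) - (b.size - 1)
        assert abs(lag) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_filter(np.zeros(100), 20.0, FPS)
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros(100), 0.1, 16.0, FPS)

    def test_bandpass_removes_dc(self):
        y = bandpass_filter(np.full(3000, 5.0), 0.1, 6.0, FPS)
        assert np.abs(y).max() < 1e-6

    @pytest.mark.parametrize("freq, min_gain, max_gain", [
        (1.0, 0.95, 1.05),   # pass band
        (10.0, 0.0, 0.10),   # stop band
    ])
    def test_bandpass_gain(self, freq, min_gain, max_gain):
        t = np.arange(0, 120, 1 / FPS)
        y = bandpass_filter(np.sin(2 * np.pi * freq * t), 0.1, 6.0, FPS)
        amp = np.abs(y[900:-900]).max()
        assert min_gain <= amp <= max_gain

    def test_linearity(self, rng):
        x, y = rng.standard_normal((2, 2000))
        a, b = 2.3, -0.7
        lhs = bandpass_filter(a * x + b * y, 0.1, 6.0, FPS)
        rhs = a * bandpass_filter(x, 0.1, 6.0, FPS) + b * bandpass_filter(y, 0.1, 6.0, FPS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)


class TestDff:
    times = np.arange(-6.0, 3.0, 1 / FPS)

    def test_constant_trace_gives_zero(self):
        dff, _ = compute_dff(np.full_like(self.times, 4.0), self.times)
        np.testing.assert_allclose(dff, 0.0)

    def test_baseline_two_analysis_three_gives_half(self):
        trace = np.where(self.times < -3.0, 2.0, 3.0)
        dff, tout = compute_dff(trace, self.times, analysis_window_s=(-3.0, 3.0))
        np.testing.assert_allclose(dff, 0.5)
        # baseline span is [-6, -3): exactly the 3 s preceding a +-3 s window
        assert tout[0] >= -3.0 and tout[-1] < 3.0

    def test_zero_baseline_error(self):
        trace = np.where(self.times < -3.0, 0.0, 1.0)
        with pytest.raises(DegenerateDataError):
            compute_dff(trace, self.times)

    def test_insufficient_history_error(self):
        t = np.arange(-4.0, 3.0, 1 / FPS)  # baseline needs -6 s
        with pytest.raises(InsufficientDataError):
            compute_dff(np.ones_like(t), t)


def _toy_session(event_times, duration_s=100.0, n_areas=3, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * FPS)
    return Session(neural=rng.standard_normal((n_areas, n)).astype(np.float32),
                   fps_neural=FPS, area_labels=[f"a{i}" for i in range(n_areas)],
                   events=EventTable({"lever_rewarded": event_times}),
                   session_id="toy")


class TestExtractTrials:
    def test_boundary_events_dropped(self):
        s = _toy_session([10.0, 50.0], duration_s=100.0)
        ts = extract_trials(s, "lever_rewarded", window_s=(-15.0, 15.0))
        assert ts.n_trials == 1            # the 10 s event underflows
        assert ts.provenance[0][1] == 50.0

    def test_all_interior_kept(self):
        times = np.linspace(20, 80, 40)
        s = _toy_session(times)
        ts = extract_trials(s, "lever_rewarded", window_s=(-15.0, 15.0))
        assert ts.n_trials == 40
        assert [p[1] for p in ts.provenance] == list(times)

    def test_t0_alignment_identity(self):
        s = _toy_session([50.017])
        ts = extract_trials(s, "lever_rewarded", window_s=(-2.0, 2.0))
        i0 = ts.t0_index()
        assert abs(ts.times_s[i0]) < 1e-9
        frame = int(round(50.017 * FPS))
        np.testing.assert_array_equal(ts.data[0, :, i0], s.neural[:, frame])


class TestControlTriggers:
    def test_gap_constraint_and_determinism(self):
        s = _toy_session([30.0, 60.0], duration_s=120.0)
        t1 = sample_control_triggers(s, 10, min_gap_s=3.0, seed=1, window_s=(-5, 5))
        t2 = sample_control_triggers(s, 10, min_gap_s=3.0, seed=1, window_s=(-5, 5))
        np.testing.assert_array_equal(t1, t2)
        for lever in (30.0, 60.0):
            assert np.abs(t1 - lever).min() > 3.0

    def test_uniform_when_event_free(self):
        """KS vs uniform p > 0.01 in >= 95% of 100 replicates."""
        s = _toy_session([], duration_s=200.0)
        lo, hi = 5.0, 195.0
        ok = 0
        for seed in range(100):
            t = sample_control_triggers(s, 60, seed=seed, window_s=(-5, 5))
            p = stats.kstest((t - lo) / (hi - lo), "uniform").pvalue
            ok += p > 0.01
        assert ok >= 95


class TestPcaDenoise:
    def _trials(self, rank, n_trials=20, n_feat=8, n_frames=31, seed=0):
        rng = np.random.default_rng(seed)
        basis = rng.standard_normal((rank, n_feat))
        scores = rng.standard_normal((n_trials, n_frames, rank))
        data = np.einsum("tfr,rn->tnf", scores, basis).transpose(0, 1, 2)
        data = np.transpose(np.einsum("tfr,rn->tfn", scores, basis), (0, 2, 1))
        times = (np.arange(n_frames) - n_frames // 2) / FPS
        from premove.preprocess import TrialSet
        return TrialSet(data=data, times_s=times, label="behavior",
                        feature_desc=[f"a{i}" for i in range(n_feat)],
                        provenance=[("s", float(i)) for i in range(n_trials)],
                        fps=FPS)

    def test_exact_low_rank_recovered(self):
        ts = self._trials(rank=3)
        proj, basis = pca_denoise(ts, var_target=0.95)
        assert proj.n_features == 3
        from premove.preprocess import pca_reconstruct
        rec = pca_reconstruct(proj, basis)
        np.testing.assert_allclose(rec, ts.data, atol=1e-8)

    def test_var_target_met_and_orthonormal(self):
        ts = self._trials(rank=8)
        proj, basis = pca_denoise(ts, var_target=0.95)
        assert basis.explained_variance_ratio_.sum() >= 0.95
        B = basis.components_
        np.testing.assert_allclose(B @ B.T, np.eye(B.shape[0]), atol=1e-10)

    def test_explained_variance_nondecreasing_in_k(self):
        ts = self._trials(rank=8)
        evs = []
        for k in range(1, 8):
            _, basis = pca_denoise(ts, fixed_k=k)
            evs.append(basis.explained_variance_ratio_.sum())
        assert np.all(np.diff(evs) >= -1e-12)

    def test_shared_basis_application(self):
        ts1, ts2 = self._trials(rank=4, seed=1), self._trials(rank=4, seed=2)
        _, basis = pca_denoise(ts1)
        proj2, basis2 = pca_denoise(ts2, basis=basis)
        assert basis2 is basis
        assert proj2.n_features == basis.n_components_


class TestConcatSessions:
    def _session(self, n_events, seed, n_areas=10, duration_s=400.0):
        rng = np.random.default_rng(seed)
        times = np.linspace(20, duration_s - 20, n_events)
        n = int(duration_s * FPS)
        # correlated areas so PCA is meaningful
        latent = rng.standard_normal((4, n))
        mix = rng.standard_normal((n_areas, 4))
        neural = (mix @ latent + 0.1 * rng.standard_normal((n_areas, n))).astype(np.float32)
        return Session(neural=neural, fps_neural=FPS,
                       area_labels=[f"a{i}" for i in range(n_areas)],
                       events=EventTable({"lever_rewarded": times}),
                       session_id=f"s{seed}")

    def test_pooling_until_min_trials(self):
        sessions = [self._session(80, seed) for seed in range(4)]
        ts = concat_sessions(sessions, window_s=(-5, 5), min_trials=200, seed=0)
        assert ts.n_trials == 240            # three sessions of 80 needed
        assert ts.n_features == 10           # fixed_k capped at n_areas

    def test_fixed_k_20_with_enough_features(self):
        sessions = [self._session(90, seed, n_areas=25) for seed in range(3)]
        ts = concat_sessions(sessions, window_s=(-5, 5), min_trials=250, seed=0)
        assert ts.n_trials == 270
        assert ts.n_features == 20

    def test_seeded_determinism(self):
        sessions = [self._session(80, seed) for seed in range(3)]
        a = concat_sessions(sessions, window_s=(-5, 5), min_trials=200, seed=5)
        b = concat_sessions(sessions, window_s=(-5, 5), min_trials=200, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_insufficient_trials_error(self):
        with pytest.raises(InsufficientDataError):
            concat_sessions([self._session(30, 0)], window_s=(-5, 5), min_trials=200)
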