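"""Filtering, dF/F0, peri-event trial extraction, control sampling, PCA denoising.

Filters are 4th-order Butterworth; zero-phase mode is a forward-backward pass
(scipy ``filtfilt``), causal mode is a single pass whose group delay is
corrected by advancing the output by ``round(fps / fc)`` samples, padding the
tail with the last filtered value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from .exceptions import (DegenerateDataError, FeasibilityError,
                         InsufficientDataError, ParameterError)
from .session import LEVER_KINDS, Session

logger = logging.getLogger(__name__)

__all__ = [
    "TrialSet", "lowpass_filter", "bandpass_filter", "compute_dff",
    "extract_trials", "extract_trials_at_times", "sample_control_triggers",
    "pca_denoise", "concat_sessions",
]


@dataclass
class TrialSet:
    """Aligned peri-event tensor: ``data[trial, feature, window_frame]``.

    ``times_s`` is the peri-event time axis (t = 0 at the event);
    ``provenance`` records ``(session_id, event_time_s)`` per trial;
    ``feature_desc`` names each feature row (area labels, or ``pc<k>`` after
    PCA denoising, in which case ``pca_model`` holds the attached basis).
    """

    data: np.ndarray
    times_s: np.ndarray
    label: str
    feature_desc: list[str]
    provenance: list[tuple[str, float]]
    fps: float
    pca_model: PCA | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError("TrialSet data must be (trials, features, frames)")
        if self.data.shape[2] != self.times_s.size:
            raise ParameterError("times_s length must match window frames")
        if np.any(np.diff(self.times_s) <= 0):
            raise ParameterError("times_s must be strictly increasing")
        if np.abs(self.times_s).min() > 0.5 / self.fps:
            raise ParameterError("times_s must include t = 0")
        if len(self.provenance) != self.data.shape[0]:
            raise ParameterError("provenance length must equal n_trials")
        if len(self.feature_desc) != self.data.shape[1]:
            raise ParameterError("feature_desc length must equal n_features")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def t0_index(self) -> int:
        return int(np.argmin(np.abs(self.times_s)))

    def select_features(self, names: Sequence[str]) -> "TrialSet":
        """Restrict to the named feature rows (order preserved as given)."""
        idx = []
        for name in names:
            if name not in self.feature_desc:
                raise KeyError(f"unknown feature {name!r}")
            idx.append(self.feature_desc.index(name))
        return replace(self, data=self.data[:, idx, :], feature_desc=list(names),
                       pca_model=None)


def _butter(order, cutoff, fps, btype):
    return signal.butter(order, cutoff, btype=btype, fs=fps)


def lowpass_filter(trace, fc: float, fps: float, mode: str = "zero_phase",
                   order: int = 4) -> np.ndarray:
    """Low-pass a 1-D series at ``fc`` Hz.

    ``zero_phase`` applies forward-backward Butterworth filtering (no delay).
    ``causal`` applies a one-pass linear-phase FIR low-pass whose group delay
    is exactly ``round(fps / fc)`` samples and advances the output by that
    amount, padding the tail with the last value — so the corrected causal
    output aligns with the zero-phase output. (An IIR one-pass filter has a
    shorter, frequency-dependent delay and cannot be corrected exactly by
    this shift.)
    """
    trace = np.asarray(trace, dtype=float)
    if not (0 < fc < fps / 2):
        raise ParameterError(f"fc must lie in (0, Nyquist); got {fc} at fps {fps}")
    if mode == "zero_phase":
        b, a = _butter(order, fc, fps, "lowpass")
        return signal.filtfilt(b, a, trace)
    if mode == "causal":
        shift = int(round(fps / fc))
        b = signal.firwin(2 * shift + 1, fc, fs=fps)
        # start from the filter's DC steady state so a constant passes unchanged
        zi = signal.lfilter_zi(b, [1.0]) * trace[0]
        y, _ = signal.lfilter(b, [1.0], trace, zi=zi)
        if shift >= y.size:
            raise ParameterError("trace shorter than the causal delay correction")
        out = np.empty_like(y)
        out[: y.size - shift] = y[shift:]
        out[y.size - shift:] = y[-1]
        return out
    raise ParameterError(f"unknown mode {mode!r}")


def causal_shift_samples(fc: float, fps: float) -> int:
    """Delay correction applied in causal mode: round(fps * 1/fc) samples."""
    return int(round(fps / fc))


def bandpass_filter(trace, lo: float, hi: float, fps: float, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass (Butterworth); removes DC, output mean ~ 0."""
    trace = np.asarray(trace, dtype=float)
    if not (0 < lo < hi < fps / 2):
        raise ParameterError(f"band ({lo}, {hi}) invalid at fps {fps}")
    b, a = _butter(order, (lo, hi), fps, "bandpass")
    return signal.filtfilt(b, a, trace)


def compute_dff(trace, times_s, analysis_window_s=(-3.0, 3.0)) -> tuple[np.ndarray, np.ndarray]:
    """dF/F0 over a peri-event analysis window.

    F0 is the mean of the baseline window immediately preceding the analysis
    window, of length equal to the pre-event part of the analysis window: for
    an analysis window (a0, a1) with a0 < 0 the baseline spans [2*a0, a0).
    Returns ``(dff, times)`` restricted to the analysis window.
    """
    trace = np.asarray(trace, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    a0, a1 = analysis_window_s
    if not (a0 < 0 <= a1):
        raise ParameterError("analysis window must start before t = 0")
    b0 = 2 * a0
    if times_s[0] > b0 + 1e-9:
        raise InsufficientDataError(
            f"trace starts at {times_s[0]:.3f} s; baseline needs {b0:.3f} s")
    base = (times_s >= b0) & (times_s < a0)
    inwin = (times_s >= a0) & (times_s < a1)
    f0 = trace[base].mean()
    if f0 == 0:
        raise DegenerateDataError("baseline F0 is zero; dF/F0 undefined")
    return (trace[inwin] - f0) / f0, times_s[inwin]


def _window_frames(window_s, fps):
    i0 = int(round(window_s[0] * fps))
    i1 = int(round(window_s[1] * fps))
    return i0, i1


def extract_trials_at_times(session: Session, times, window_s, label: str) -> TrialSet:
    """Peri-event tensor at the given trigger times; out-of-bounds triggers dropped."""
    fps = session.fps_neural
    i0, i1 = _window_frames(window_s, fps)
    axis = (np.arange(i0, i1)) / fps
    trials, prov = [], []
    dropped = 0
    for te in np.asarray(times, dtype=float):
        c = int(round(te * fps))
        if c + i0 < 0 or c + i1 > session.n_frames:
            dropped += 1
            continue
        trials.append(session.neural[:, c + i0: c + i1])
        prov.append((session.session_id, float(te)))
    if dropped:
        logger.info("extract_trials: dropped %d/%d events (window out of bounds)",
                    dropped, len(np.atleast_1d(times)))
    if not trials:
        raise InsufficientDataError("no events with a full window inside the session")
    data = np.stack(trials).astype(np.float64)
    return TrialSet(data=data, times_s=axis, label=label,
                    feature_desc=list(session.area_labels), provenance=prov, fps=fps)


def extract_trials(session: Session, event_kind: str, window_s=(-15.0, 15.0)) -> TrialSet:
    """One behavior trial per event of ``event_kind`` whose window fits the session."""
    times = session.events.times(event_kind)
    if times.size == 0:
        raise InsufficientDataError(f"no events of kind {event_kind!r}")
    return extract_trials_at_times(session, times, window_s, label="behavior")


def sample_control_triggers(session: Session, n: int, min_gap_s: float = 3.0,
                            seed: int | None = None,
                            window_s=(-15.0, 15.0)) -> np.ndarray:
    """``n`` random times >= ``min_gap_s`` from every lever event, full window inside.

    Control segments may still contain licks or paw movements: matching the
    conservative definition of "random activity" used for the control class.
    """
    rng = np.random.default_rng(seed)
    lever = np.sort(np.concatenate([session.events.times(k) for k in LEVER_KINDS]))
    lo, hi = -window_s[0], session.duration_s - window_s[1]
    if hi <= lo:
        raise FeasibilityError("session shorter than the peri-event window")
    out = []
    max_draw = max(10000, 1000 * n)
    drawn = 0
    while len(out) < n and drawn < max_draw:
        batch = rng.uniform(lo, hi, size=max(n, 64))
        drawn += batch.size
        if lever.size:
            d = np.min(np.abs(batch[:, None] - lever[None, :]), axis=1)
            batch = batch[d > min_gap_s]
        out.extend(batch.tolist())
    if len(out) < n:
        raise FeasibilityError(
            f"could not place {n} control triggers >= {min_gap_s} s from lever events")
    return np.sort(np.asarray(out[:n]))


def _stack_frames(data: np.ndarray) -> np.ndarray:
    # (trials, features, frames) -> (trials*frames, features)
    return np.transpose(data, (0, 2, 1)).reshape(-1, data.shape[1])


def _unstack_frames(flat: np.ndarray, n_trials: int, n_frames: int) -> np.ndarray:
    return np.transpose(flat.reshape(n_trials, n_frames, -1), (0, 2, 1))


def pca_denoise(trialset: TrialSet, var_target: float = 0.95,
                basis: PCA | None = None, fixed_k: int | None = None
                ) -> tuple[TrialSet, PCA]:
    """Project trials onto the leading principal components.

    The basis is fit on the trial frames arranged ``[samples, features]`` and
    keeps the smallest k with cumulative explained variance >= ``var_target``
    (or exactly ``fixed_k``). Pass ``basis`` to re-use a fitted model — the
    behavior and control sets of one session must share one basis.
    """
    X = _stack_frames(trialset.data)
    if X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 samples to fit a PCA basis")
    if basis is None:
        if not np.any(X.std(axis=0) > 0):
            raise DegenerateDataError("zero-variance data; PCA basis undefined")
        full = PCA(n_components=min(X.shape), svd_solver="full")
        full.fit(X)
        if fixed_k is not None:
            k = min(fixed_k, full.n_components_)
        else:
            cum = np.cumsum(full.explained_variance_ratio_)
            k = int(np.searchsorted(cum, var_target - 1e-12) + 1)
        basis = PCA(n_components=k, svd_solver="full")
        basis.fit(X)
    comps = basis.transform(X)
    data = _unstack_frames(comps, trialset.n_trials, trialset.n_frames)
    out = replace(trialset, data=data,
                  feature_desc=[f"pc{i}" for i in range(data.shape[1])],
                  pca_model=basis)
    return out, basis


def pca_reconstruct(trialset: TrialSet, basis: PCA) -> np.ndarray:
    """Reconstruct (trials, features, frames) data from a PCA projection."""
    comps = _stack_frames(trialset.data)
    rec = basis.inverse_transform(comps)
    return _unstack_frames(rec, trialset.n_trials, trialset.n_frames)


def concat_sessions(sessions: Sequence[Session], event_kind: str = "lever_rewarded",
                    window_s=(-15.0, 15.0), min_trials: int = 200,
                    fixed_k: int = 20, sample_frac: float = 0.03,
                    var_target: float = 0.95, seed: int | None = None) -> TrialSet:
    """Pool trials across sequential sessions under one multi-session basis.

    Each session is first denoised with its own >= ``var_target`` basis
    (project + reconstruct in feature space); a multi-session basis is then
    fit on a seeded random ``sample_frac`` sample of the concatenated frames
    and all sessions are projected with ``fixed_k`` components (capped at the
    feature dimensionality). Sessions are taken in order until the pooled
    count reaches ``min_trials``.
    """
    if not sessions:
        raise InsufficientDataError("need at least one session")
    rng = np.random.default_rng(seed)

    pooled, denoised = [], []
    for s in sessions:
        ts = extract_trials(s, event_kind, window_s)
        proj, basis = pca_denoise(ts, var_target=var_target)
        rec = pca_reconstruct(proj, basis)
        denoised.append(replace(ts, data=rec))
        pooled.append(ts.n_trials)
        if sum(pooled) >= min_trials:
            break
    if sum(pooled) < min_trials:
        raise InsufficientDataError(
            f"only {sum(pooled)} trials available; need >= {min_trials}")

    frames = np.concatenate([_stack_frames(ts.data) for ts in denoised], axis=0)
    n_sample = max(int(round(sample_frac * frames.shape[0])), 2 * fixed_k)
    idx = rng.choice(frames.shape[0], size=min(n_sample, frames.shape[0]), replace=False)
    k = min(fixed_k, frames.shape[1], idx.size)
    basis = PCA(n_components=k, svd_solver="full")
    basis.fit(frames[idx])

    parts, prov = [], []
    for ts in denoised:
        comps = basis.transform(_stack_frames(ts.data))
        parts.append(_unstack_frames(comps, ts.n_trials, ts.n_frames))
        prov.extend(ts.provenance)
    data = np.concatenate(parts, axis=0)
    return TrialSet(data=data, times_s=denoised[0].times_s, label="behavior",
                    feature_desc=[f"pc{i}" for i in range(k)], provenance=prov,
                    fps=denoised[0].fps, pca_model=basis)
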