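"""Sliding-window peri-event decoding and the earliest-decoding-time statistic.

For every 1-s feature window position a two-class SVM (behavior vs control,
sigmoid kernel) is trained under stratified k-fold cross-validation; the fold
accuracies are assigned to the window's last time point. Accuracy curves are
smoothed with a 30-step moving average, tested per time point against chance
(one-sample t-test, one-sided), corrected across the curve with
Benjamini-Hochberg, and the earliest decoding time (EDT) is the most negative
time from which every later evaluated time point remains significant; 0 means
the action was not predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, ParameterError
from .preprocess import TrialSet, extract_trials, extract_trials_at_times, \
    lowpass_filter, pca_denoise, sample_control_triggers
from .session import Session

__all__ = [
    "AccuracyCurve", "EDTResult", "train_accuracy_curve", "smooth_curve",
    "curve_significance", "bh_adjust", "compute_edt", "decode_per_area",
    "session_edt", "ks_edt_distributions",
]


@dataclass
class AccuracyCurve:
    """Per-timepoint cross-validation fold accuracies for one decoding run."""

    times_s: np.ndarray                  # assigned time of each feature window
    fold_acc: np.ndarray                 # (n_timepoints, n_folds) in [0, 1]
    params: dict
    smoothed: bool = False

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.fold_acc = np.asarray(self.fold_acc, dtype=float)
        if self.fold_acc.ndim != 2 or self.fold_acc.shape[0] != self.times_s.size:
            raise ParameterError("fold_acc must be (n_timepoints, n_folds)")
        if np.any((self.fold_acc < 0) | (self.fold_acc > 1)):
            raise ParameterError("fold accuracies must lie in [0, 1]")

    @property
    def mean(self) -> np.ndarray:
        return self.fold_acc.mean(axis=1)


@dataclass
class EDTResult:
    """Earliest decoding time with its per-timepoint evidence trace."""

    edt_s: float                         # <= 0; 0 means "not predicted"
    times_s: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float
    significant_mask: np.ndarray

    def __post_init__(self):
        if self.edt_s > 0:
            raise ParameterError("edt_s must be <= 0")


def train_accuracy_curve(behavior: TrialSet, control: TrialSet,
                         feature_window_s: float = 1.0, folds: int = 10,
                         kernel: str = "sigmoid", seed: int | None = None,
                         stride: int = 1, C: float = 1.0) -> AccuracyCurve:
    """Sliding-window cross-validated decoding of behavior vs control trials.

    Features at each window position are the flattened
    ``[n_features x window_frames]`` block per trial. One classifier is
    trained per window position per fold; all positions share the same seeded
    stratified fold partition, so fold accuracies are paired across time.
    ``stride`` subsamples the evaluation grid (1 = every frame).
    """
    if behavior.data.shape[1:] != control.data.shape[1:]:
        raise ParameterError("behavior and control trials must share shape")
    if behavior.feature_desc != control.feature_desc:
        raise ParameterError("behavior and control must share the feature basis")
    n_b, n_c = behavior.n_trials, control.n_trials
    if min(n_b, n_c) < folds:
        raise InsufficientDataError(f"need >= {folds} trials per class")

    fps = behavior.fps
    w = int(round(feature_window_s * fps))
    n_frames = behavior.n_frames
    if w < 1 or w >= n_frames:
        raise ParameterError("feature window must fit inside the trial window")

    X_all = np.concatenate([behavior.data, control.data], axis=0)
    y = np.concatenate([np.ones(n_b, dtype=int), np.zeros(n_c, dtype=int)])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    starts = np.arange(0, n_frames - w, stride)
    times = behavior.times_s[starts + w - 1]  # assigned to the window's last frame
    acc = np.empty((starts.size, folds))
    for j, s in enumerate(starts):
        X = X_all[:, :, s: s + w].reshape(len(y), -1)
        for f, (tr, te) in enumerate(splits):
            clf = SVC(kernel=kernel, C=C, gamma="scale")
            clf.fit(X[tr], y[tr])
            acc[j, f] = clf.score(X[te], y[te])

    params = dict(feature_window_s=feature_window_s, folds=folds, kernel=kernel,
                  seed=seed, stride=stride, C=C, gamma="scale",
                  n_behavior=n_b, n_control=n_c,
                  n_window_features=behavior.n_features * w,
                  n_classifiers_per_fold=int(starts.size))
    return AccuracyCurve(times_s=times, fold_acc=acc, params=params)


def smooth_curve(curve: AccuracyCurve, k: int = 30) -> AccuracyCurve:
    """Centered moving average (k samples) per fold trace; shrinking edges."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > curve.fold_acc.shape[0]:
        raise ParameterError("smoothing window longer than the curve")
    sm = (pd.DataFrame(curve.fold_acc)
          .rolling(window=k, center=True, min_periods=1).mean().to_numpy())
    return replace(curve, fold_acc=sm, smoothed=True)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    _, p_adj, _, _ = multipletests(np.asarray(p_raw, dtype=float), method="fdr_bh")
    return p_adj


def curve_significance(curve: AccuracyCurve, chance: float = 0.5,
                       alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-timepoint one-sample t-test of fold accuracies above chance + BH.

    Returns ``(p_raw, p_adj, mask)`` with Benjamini-Hochberg adjustment across
    all time points of the curve. A time point with zero fold variance gets
    p = 0 if its mean exceeds chance, else p = 1.
    """
    acc = curve.fold_acc
    p_raw = np.empty(acc.shape[0])
    for i in range(acc.shape[0]):
        a = acc[i]
        if np.ptp(a) == 0:
            p_raw[i] = 0.0 if a[0] > chance else 1.0
        else:
            p_raw[i] = stats.ttest_1samp(a, chance, alternative="greater").pvalue
    p_adj = bh_adjust(p_raw)
    mask = p_adj < alpha
    return p_raw, p_adj, mask


def compute_edt(p_adj, times_s, alpha: float = 0.05, p_raw=None) -> EDTResult:
    """Backward walk from t = 0: EDT is the most negative evaluated time t*
    such that every evaluated time in [t*, 0] is significant; isolated earlier
    significant islands are ignored. If t = 0 itself is not significant the
    action was not predicted and EDT = 0.
    """
    times_s = np.asarray(times_s, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    mask = p_adj < alpha
    at_or_before = np.flatnonzero(times_s <= 1e-9)
    if at_or_before.size == 0:
        raise ParameterError("evaluation grid must cover t <= 0")
    i0 = at_or_before[-1]  # evaluated point closest to (at or just before) t = 0
    edt = 0.0
    if mask[i0]:
        i = i0
        while i > 0 and mask[i - 1]:
            i -= 1
        edt = float(min(times_s[i], 0.0))
    return EDTResult(edt_s=edt, times_s=times_s,
                     p_raw=np.asarray(p_raw, dtype=float) if p_raw is not None else p_adj,
                     p_adj=p_adj, alpha=alpha, significant_mask=mask)


def decode_per_area(behavior: TrialSet, control: TrialSet, areas,
                    **kwargs) -> AccuracyCurve:
    """Decoding restricted to the selected areas (a bilateral pair by default).

    ``areas`` is an area base name (selects both hemispheres, e.g. ``"limb"``
    -> ``limb_L, limb_R``), a full label, or a list of labels. Requires
    trial sets still in area feature space (not PCA components).
    """
    if isinstance(areas, str):
        pair = [f for f in behavior.feature_desc
                if f == areas or f.rsplit("_", 1)[0] == areas]
        if not pair:
            raise KeyError(f"unknown area label {areas!r}")
        names = pair
    else:
        names = list(areas)
    return train_accuracy_curve(behavior.select_features(names),
                                control.select_features(names), **kwargs)


def ks_edt_distributions(edts_a, edts_b) -> tuple[float, float]:
    """Two-sample KS comparison of two EDT distributions -> (statistic, p)."""
    res = stats.ks_2samp(np.asarray(edts_a, dtype=float),
                         np.asarray(edts_b, dtype=float))
    return float(res.statistic), float(res.pvalue)


def session_edt(session: Session, event_kind: str = "lever_rewarded",
                window_s=(-15.0, 15.0), feature_window_s: float = 1.0,
                folds: int = 10, alpha: float = 0.05, var_target: float = 0.95,
                control_gap_s: float = 3.0, smooth_k: int = 30,
                stride: int = 1, seed: int | None = None,
                lowpass_hz: float | None = None, areas=None,
                max_trials: int | None = None
                ) -> tuple[AccuracyCurve, EDTResult]:
    """End-to-end single-session EDT: trials, matched controls, shared PCA
    basis, sliding-window decoding, smoothing, t-test + BH, backward walk.

    With ``lowpass_hz`` set, area traces are zero-phase low-pass filtered
    before trial extraction (feature engineering toward slow oscillations).
    With ``areas`` set, decoding is restricted to that bilateral area.
    """
    if lowpass_hz is not None:
        filt = np.stack([lowpass_filter(tr, lowpass_hz, session.fps_neural,
                                        mode="zero_phase") for tr in session.neural])
        session = Session(neural=filt, fps_neural=session.fps_neural,
                          area_labels=session.area_labels, events=session.events,
                          tracks=session.tracks, session_id=session.session_id,
                          session_index=session.session_index, meta=session.meta)

    behavior = extract_trials(session, event_kind, window_s)
    if max_trials is not None and behavior.n_trials > max_trials:
        behavior = replace(behavior, data=behavior.data[:max_trials],
                           provenance=behavior.provenance[:max_trials])
    ctrl_times = sample_control_triggers(session, behavior.n_trials,
                                         min_gap_s=control_gap_s, seed=seed,
                                         window_s=window_s)
    control = extract_trials_at_times(session, ctrl_times, window_s, label="control")

    if areas is not None:
        curve = decode_per_area(behavior, control, areas,
                                feature_window_s=feature_window_s, folds=folds,
                                seed=seed, stride=stride)
    else:
        behavior, basis = pca_denoise(behavior, var_target=var_target)
        control, _ = pca_denoise(control, basis=basis)
        curve = train_accuracy_curve(behavior, control,
                                     feature_window_s=feature_window_s,
                                     folds=folds, seed=seed, stride=stride)

    # smooth_k counts frames; on a strided grid keep the same 1-s span
    k_eff = max(1, int(round(smooth_k / stride)))
    sm = smooth_curve(curve, k=min(k_eff, curve.fold_acc.shape[0]))
    p_raw, p_adj, _ = curve_significance(sm, alpha=alpha)
    edt = compute_edt(p_adj, sm.times_s, alpha=alpha, p_raw=p_raw)
    return sm, edt
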