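"""Across-trial variance traces and the earliest-variance-decrease time (EVDT).

The EVDT of a session is the earliest peri-event time at which the
across-trial variance stays beyond a baseline-derived threshold (baseline
mean minus k baseline standard deviations, computed over a far pre-event
window) for a full 1-s sliding window, restricted to a validity range around
the action. An ``absolute`` mode detects changes of either sign (for subjects
whose pre-movement variance increases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateDataError, InsufficientDataError, ParameterError
from .preprocess import TrialSet

__all__ = ["EVDTResult", "variance_trace", "compute_evdt"]


@dataclass
class EVDTResult:
    """Variance-change onset for one area/session."""

    evdt_s: float | None               # None = undetected
    mode: str
    variance_trace: np.ndarray
    times_s: np.ndarray
    threshold: float
    baseline_mean: float
    baseline_sd: float

    @property
    def detected(self) -> bool:
        return self.evdt_s is not None


def variance_trace(trialset: TrialSet, area: str) -> np.ndarray:
    """Across-trial variance (ddof=1) at each peri-event time point for one area."""
    if trialset.n_trials < 5:
        raise InsufficientDataError("need at least 5 trials for a variance trace")
    if area not in trialset.feature_desc:
        raise KeyError(f"unknown area {area!r}")
    i = trialset.feature_desc.index(area)
    return trialset.data[:, i, :].var(axis=0, ddof=1)


def compute_evdt(var_trace, times_s, baseline_window_s=(-30.0, -15.0),
                 k: float = 2.0, valid_range_s=(-6.0, 0.5), mode: str = "decrease",
                 window_s: float = 1.0, smooth: bool = False) -> EVDTResult:
    """Earliest time at which the variance crosses the baseline threshold.

    The baseline mean and sd use the raw (unsmoothed) variance trace over
    ``baseline_window_s``; with ``smooth`` the detection trace is first
    Savitzky-Golay filtered (31 samples, order 3). The qualifying time t is
    the earliest for which every sample in [t, t + window_s) satisfies the
    criterion (decrease: v < mean - k*sd; absolute: |v - mean| > k*sd); if
    that earliest time falls outside ``valid_range_s`` the change is treated
    as undetected.
    """
    v = np.asarray(var_trace, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if v.shape != t.shape:
        raise ParameterError("variance trace and time axis must align")
    if mode not in ("decrease", "absolute"):
        raise ParameterError(f"unknown mode {mode!r}")
    b0, b1 = baseline_window_s
    base = (t >= b0) & (t < b1)
    if base.sum() < 5:
        raise ParameterError("trace does not cover the baseline window")
    mu_b = float(v[base].mean())
    sd_b = float(v[base].std(ddof=1))
    if sd_b == 0:
        if np.ptp(v) == 0:
            # perfectly constant trace: nothing can cross any threshold
            return EVDTResult(evdt_s=None, mode=mode, variance_trace=v, times_s=t,
                              threshold=mu_b, baseline_mean=mu_b, baseline_sd=0.0)
        raise DegenerateDataError("zero baseline variance-of-variance")

    det = v
    if smooth:
        if v.size <= 31:
            raise InsufficientDataError("trace too short for Savitzky-Golay smoothing")
        det = savgol_filter(v, 31, 3)

    if mode == "decrease":
        ok = det < mu_b - k * sd_b
        threshold = mu_b - k * sd_b
    else:
        ok = np.abs(det - mu_b) > k * sd_b
        threshold = k * sd_b

    dt = float(np.median(np.diff(t)))
    w = max(int(round(window_s / dt)), 1)
    # scan from after the baseline window; left-closed sliding window, one-frame step
    start = int(np.searchsorted(t, b1))
    evdt = None
    for i in range(start, v.size - w + 1):
        if ok[i: i + w].all():
            evdt = float(t[i])
            break
    if evdt is not None and not (valid_range_s[0] <= evdt <= valid_range_s[1]):
        evdt = None
    return EVDTResult(evdt_s=evdt, mode=mode, variance_trace=v, times_s=t,
                      threshold=threshold, baseline_mean=mu_b, baseline_sd=sd_b)
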