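"""Slow-oscillation phase statistics and power spectra.

Single-trial sinusoid fits over the last seconds before the action give a
phase at t = 0 per trial; circular statistics (mean, resultant length,
Rayleigh uniformity test) summarize the phase-of-action bias. Welch spectra
of trial or session-average traces give peak frequency and power, and simple
Pearson trends track longitudinal changes across sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .exceptions import InsufficientDataError, ParameterError

__all__ = [
    "PhaseFit", "fit_sinusoid", "phase_stats", "rayleigh_test",
    "interarea_phase_corr", "psd_peak", "longitudinal_trend", "wrap_angle",
]


def wrap_angle(phi):
    """Wrap angle(s) to (-pi, pi]."""
    return -(np.mod(-np.asarray(phi) + np.pi, 2 * np.pi) - np.pi)


@dataclass
class PhaseFit:
    """Single-trial sinusoid fit A*sin(2*pi*f*t + phi) + c over a pre-event window."""

    amplitude: float
    freq: float                      # Hz, > 0
    phase_at_zero: float             # radians in (-pi, pi]
    offset: float
    fit_rmse: float
    converged: bool = True
    area: str | None = None
    provenance: tuple | None = None


def _linear_sine_fit(t, y, f):
    """Least-squares amplitude/phase/offset at fixed frequency; returns (rss, A, phi, c)."""
    M = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t),
                         np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    a, b, c = coef
    resid = y - M @ coef
    A = float(np.hypot(a, b))
    phi = float(np.arctan2(b, a))  # a sin + b cos = A sin(theta + phi)
    return float(resid @ resid), A, phi, c


def fit_sinusoid(trace, times_s, fit_window_s=(-5.0, 0.0),
                 freq_bounds=(0.05, 2.0), coarse_grid=None) -> PhaseFit:
    """Fit A*sin(2*pi*f*t + phi) + c to one peri-event trace.

    The frequency is scanned on a coarse grid with closed-form amplitude/
    phase/offset at each candidate (the sinusoid model is linear given f),
    then refined by bounded nonlinear least squares. The phase at t = 0 is
    phi wrapped to (-pi, pi] — the intersection of the fit with the t = 0
    line. A non-convergent refinement returns the grid solution flagged
    ``converged=False``.
    """
    trace = np.asarray(trace, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    sel = (times_s >= fit_window_s[0]) & (times_s <= fit_window_s[1])
    if sel.sum() < 8:
        raise InsufficientDataError("fit window contains too few samples")
    t, y = times_s[sel], trace[sel]

    if coarse_grid is None:
        coarse_grid = np.arange(freq_bounds[0], min(freq_bounds[1], 1.0) + 1e-9, 0.01)
    best = min((_linear_sine_fit(t, y, f) + (f,) for f in coarse_grid),
               key=lambda r: r[0])
    rss0, A0, phi0, c0, f0 = best

    def model(t_, A, f, phi, c):
        return A * np.sin(2 * np.pi * f * t_ + phi) + c

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, t, y, p0=[max(A0, 1e-6), f0, phi0, c0],
                bounds=([0.0, freq_bounds[0], -2 * np.pi, -np.inf],
                        [np.inf, freq_bounds[1], 2 * np.pi, np.inf]),
                maxfev=2000)
        A, f, phi, c = popt
        resid = y - model(t, *popt)
        rss = float(resid @ resid)
        if rss > rss0 * (1 + 1e-9):  # refinement made it worse: keep grid solution
            A, f, phi, c, rss = A0, f0, phi0, c0, rss0
    except RuntimeError:
        A, f, phi, c, rss = A0, f0, phi0, c0, rss0
        converged = False

    if A < 0:
        A, phi = -A, phi + np.pi
    return PhaseFit(amplitude=float(A), freq=float(f),
                    phase_at_zero=float(wrap_angle(phi)), offset=float(c),
                    fit_rmse=float(np.sqrt(rss / t.size)), converged=converged)


def phase_stats(phases, n_boot: int = 0, seed: int | None = None
                ) -> tuple[float, float, float]:
    """Circular mean, resultant length R, and Rayleigh uniformity p.

    The Rayleigh p uses the standard finite-n corrected series; with
    ``n_boot`` > 0 a Monte-Carlo uniform-null p-value is returned instead
    (useful at very small n).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 5:
        raise InsufficientDataError("need at least 5 phases")
    z = np.exp(1j * phases).mean()
    circ_mean = float(np.angle(z))
    r = float(np.abs(z))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        null = np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, size=(n_boot, n))).mean(axis=1))
        p = float((np.sum(null >= r) + 1) / (n_boot + 1))
    else:
        p = rayleigh_test(r, n)
    return circ_mean, r, p


def rayleigh_test(r: float, n: int) -> float:
    """Rayleigh uniformity p-value with the finite-n correction (Zar)."""
    z = n * r * r
    p = np.exp(-z) * (1 + (2 * z - z * z) / (4 * n)
                      - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4) / (288 * n * n))
    return float(np.clip(p, 0.0, 1.0))


def interarea_phase_corr(per_area_phases: np.ndarray,
                         area_labels=None) -> np.ndarray:
    """Pairwise circular-circular correlation (Fisher-Lee form) between areas.

    ``per_area_phases`` is (n_trials, n_areas). Entries for areas with
    (near-)constant phase are undefined and returned as NaN with a warning.
    The matrix is symmetric with unit diagonal.
    """
    X = np.asarray(per_area_phases, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise InsufficientDataError("need a (>=5 trials, n_areas) phase matrix")
    n, m = X.shape
    # pairwise angle differences per area: sin(x_i - x_j), i < j
    sines = []
    iu = np.triu_indices(n, k=1)
    for a in range(m):
        d = X[:, a][:, None] - X[:, a][None, :]
        sines.append(np.sin(d[iu]))
    sines = np.stack(sines)           # (areas, n_pairs)
    norms = np.sqrt((sines ** 2).sum(axis=1))
    C = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            denom = norms[a] * norms[b]
            if denom == 0:
                warnings.warn("constant phases in an area: correlation undefined")
                C[a, b] = C[b, a] = np.nan
            else:
                C[a, b] = C[b, a] = float((sines[a] * sines[b]).sum() / denom)
    return C


def psd_peak(trace, fps: float, band=(0.05, 2.0), nperseg: int = 512
             ) -> tuple[float, float]:
    """Peak frequency and power of the Welch PSD within ``band``.

    Welch parameters: Hann window, segment length min(len(trace), nperseg),
    50% overlap. The trace must span at least ``2 / band[0]`` seconds.
    """
    trace = np.asarray(trace, dtype=float)
    lo, hi = band
    if not (0 < lo < hi):
        raise ParameterError("band must satisfy 0 < lo < hi")
    if trace.size / fps < 2.0 / lo:
        raise InsufficientDataError(
            f"trace spans {trace.size / fps:.1f} s; need >= {2.0 / lo:.1f} s for band {band}")
    nps = min(trace.size, nperseg)
    f, p = signal.welch(trace, fs=fps, window="hann", nperseg=nps,
                        noverlap=nps // 2, detrend="constant")
    sel = (f >= lo) & (f <= hi)
    if not sel.any():
        raise ParameterError("band contains no frequency bins")
    i = np.argmax(p[sel])
    return float(f[sel][i]), float(p[sel][i])


def longitudinal_trend(session_index, values, burn_in: int = 7
                       ) -> tuple[float, float]:
    """Pearson correlation of a per-session value against session index.

    Sessions with index < ``burn_in`` are discarded (habituation burn-in,
    one week by default). Constant values give (nan, nan) with a warning.
    """
    idx = np.asarray(session_index, dtype=float)
    vals = np.asarray(values, dtype=float)
    sel = idx >= burn_in
    idx, vals = idx[sel], vals[sel]
    if idx.size < 3:
        raise InsufficientDataError("need at least 3 sessions after burn-in")
    if np.ptp(vals) == 0 or np.ptp(idx) == 0:
        warnings.warn("constant input: Pearson correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(idx, vals)
    return float(r), float(p)
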