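"""Behavioral event processing.

Movement-initiation detection from body tracks, lockout filtering of target
events against preceding movements (evaluated on a 0.250-s bin grid),
pooling of locked-out trials into overlapping sliding groups, quiescent-bout
selection, and a PCA embedding of binarized pre-event movement patterns for
stereotypy screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from .exceptions import DegenerateDataError, InsufficientDataError, ParameterError, ValidationError
from .session import BODY_KINDS, LEVER_KINDS, BodyTrack, EventTable

__all__ = [
    "LockoutSpec", "detect_initiations", "apply_lockout", "pool_lockout_trials",
    "select_quiescent_bouts", "stereotypy_embedding", "movement_speed",
]


@dataclass
class LockoutSpec:
    """How to evaluate quiescence before a target event.

    ``blocked_kinds`` are the event kinds that break quiescence; the lockout
    span is binned at ``bin_s`` resolution and, with ``edge_allowance``, the
    first bin of the span and the bin immediately before the event (the
    -0.250 s bin) may contain movement — an allowance for the coarser video
    clock relative to the neural clock.
    """

    lockout_s: float
    bin_s: float = 0.250
    edge_allowance: bool = True
    blocked_kinds: tuple[str, ...] = LEVER_KINDS

    def __post_init__(self):
        if self.lockout_s < 0:
            raise ValidationError("lockout_s must be >= 0")
        if self.bin_s <= 0:
            raise ValidationError("bin_s must be > 0")


def _smooth_positions(xy: np.ndarray, smoothing: str) -> np.ndarray:
    n = xy.shape[0]
    if smoothing == "moving_mean_30":
        if n <= 30:
            raise InsufficientDataError("track shorter than the smoothing window")
        kernel = np.ones(30) / 30.0
        out = np.column_stack([
            np.convolve(np.pad(xy[:, d], 15, mode="edge"), kernel, mode="same")[15:-15]
            for d in range(2)
        ])
        return out
    if smoothing == "savgol_31_3":
        if n <= 31:
            raise InsufficientDataError("track shorter than the smoothing window")
        return savgol_filter(xy, 31, 3, axis=0)
    raise ParameterError(f"unknown smoothing {smoothing!r}")


def movement_speed(xy: np.ndarray, fps: float, smoothing: str = "savgol_31_3") -> np.ndarray:
    """Per-frame speed (px/s) of a smoothed (n, 2) position trace; length n-1."""
    sm = _smooth_positions(np.asarray(xy, dtype=float), smoothing)
    return np.linalg.norm(np.diff(sm, axis=0), axis=1) * fps


def detect_initiations(xy: np.ndarray, fps: float, k_std: float = 3.0,
                       refractory_s: float = 3.0,
                       smoothing: str = "savgol_31_3") -> np.ndarray:
    """Movement initiation times (s) for one body-part position trace.

    An initiation is an upward crossing of ``k_std`` times the whole-session
    standard deviation of speed; initiations preceded by another initiation of
    the same feature within ``refractory_s`` are removed.
    """
    speed = movement_speed(xy, fps, smoothing)
    sd = speed.std()
    # numeric floor: a still track shows only float noise in the smoothed speed
    floor = 1e-8 * max(1.0, float(np.abs(xy).max())) * fps
    if sd <= floor:
        return np.empty(0)
    thr = k_std * sd
    above = speed > thr
    crossings = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    times = (crossings + 1) / fps  # diff sample i spans frames (i, i+1)
    kept = []
    last = -np.inf
    for t in times:
        if t - last > refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def apply_lockout(events: EventTable, target_kind: str, spec: LockoutSpec) -> np.ndarray:
    """Target events whose preceding ``lockout_s`` contains no blocked events.

    Quiescence is evaluated on a ``bin_s`` grid. With ``edge_allowance`` the
    first bin of the lockout span and the bin immediately before the event may
    contain movement. Targets whose lockout window extends before the session
    start are dropped. The target event itself never blocks.
    """
    targets = events.times(target_kind)
    if spec.lockout_s == 0:
        return targets.copy()

    blocked_times = np.concatenate(
        [events.times(k) for k in spec.blocked_kinds]) if spec.blocked_kinds else np.empty(0)
    eps = 1e-9
    blocked_bins = set(np.floor((blocked_times + eps) / spec.bin_s).astype(int))

    survivors = []
    for te in targets:
        if te - spec.lockout_s < 0:
            continue
        first_bin = int(np.floor((te - spec.lockout_s + eps) / spec.bin_s))
        last_bin = int(np.ceil((te - eps) / spec.bin_s)) - 1  # the -bin_s..0 bin
        check = set(range(first_bin, last_bin + 1))
        check.discard(int(np.floor((te + eps) / spec.bin_s)))  # own bin never blocks
        if spec.edge_allowance:
            check.discard(first_bin)
            check.discard(last_bin)
        else:
            # exclude the target event itself if it shares a bin with a blocked kind
            pass
        hit = False
        for b in check:
            if b in blocked_bins:
                # ignore bins whose only occupant is the target event itself
                tb = blocked_times[(blocked_times + eps >= b * spec.bin_s)
                                   & (blocked_times + eps < (b + 1) * spec.bin_s)]
                if np.any(np.abs(tb - te) > eps):
                    hit = True
                    break
        if not hit:
            survivors.append(te)
    return np.asarray(survivors)


def pool_lockout_trials(n_trials: int, group_size: int = 200, stride: int = 50,
                        min_size: int = 50) -> list[tuple[int, int]]:
    """Overlapping sliding groups ``[s, min(s + group_size, n))`` over ordered trials.

    Groups are emitted for s = 0, stride, 2*stride, ... while the group still
    holds at least ``min_size`` trials (503 trials with the defaults give the
    ten groups 0-200, 50-250, ..., 450-503).
    """
    if n_trials < min_size:
        raise InsufficientDataError(f"{n_trials} trials < minimum group size {min_size}")
    groups: list[tuple[int, int]] = []
    s = 0
    while min(s + group_size, n_trials) - s >= min_size:
        groups.append((s, min(s + group_size, n_trials)))
        s += stride
    return groups


def select_quiescent_bouts(events: EventTable, target_kind: str = "left_paw",
                           lever_pre_s: float = 15.0, lever_post_s: float = 5.0,
                           body_quiescence_s: float = 5.0) -> pd.DataFrame:
    """Target initiations isolated from lever pulls and preceded by body quiescence.

    Keeps target initiations with (a) no lever event (rewarded or unrewarded)
    in [-lever_pre_s, +lever_post_s] and (b) no initiation of any tracked body
    feature in the preceding ``body_quiescence_s``. Returns a DataFrame with
    ``time_s`` and the pre-event quiescence duration ``quiescence_s`` (time
    since the last preceding body or lever event, for raster ordering).
    """
    targets = events.times(target_kind)
    lever = np.sort(np.concatenate([events.times(k) for k in LEVER_KINDS]))
    body = np.sort(np.concatenate([events.times(k) for k in BODY_KINDS]))

    rows = []
    for te in targets:
        if lever.size and np.any((lever >= te - lever_pre_s) & (lever <= te + lever_post_s)):
            continue
        prior_body = body[(body < te) & (body >= te - body_quiescence_s)]
        if prior_body.size:
            continue
        everything = np.concatenate([lever, body])
        before = everything[everything < te]
        q = float(te - before.max()) if before.size else float(te)
        rows.append((float(te), q))
    return pd.DataFrame(rows, columns=["time_s", "quiescence_s"])


def stereotypy_embedding(tracks: BodyTrack, event_times, window_s=(-10.0, 0.0),
                         k_std: float = 3.0,
                         features=("left_paw", "right_paw", "tongue")) -> np.ndarray:
    """2-D PCA embedding of binarized pre-event movement patterns, one point per trial.

    Movement is binarized per body part with the initiation detector's speed
    threshold (``k_std`` x whole-session speed sd), windows are flattened with
    body parts concatenated, and the first two principal-component scores are
    returned (mean-centered by construction).
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size < 3:
        raise InsufficientDataError("need at least 3 trials for an embedding")
    fps = tracks.fps_video
    present = [f for f in features if f in tracks.features]
    if not present:
        raise ParameterError("none of the requested features are tracked")

    binarized = {}
    for f in present:
        speed = movement_speed(tracks.features[f], fps)
        thr = k_std * speed.std()
        binarized[f] = (speed > thr).astype(float)

    i0 = int(round(window_s[0] * fps))
    i1 = int(round(window_s[1] * fps))
    rows = []
    for te in event_times:
        c = int(round(te * fps))
        if c + i0 < 0 or c + i1 > len(next(iter(binarized.values()))):
            continue
        rows.append(np.concatenate([binarized[f][c + i0: c + i1] for f in present]))
    if len(rows) < 3:
        raise InsufficientDataError("fewer than 3 trials with a full window")
    X = np.stack(rows)
    if not np.any(X):
        raise DegenerateDataError("no movement detected in any trial window")
    pca = PCA(n_components=2, svd_solver="full")
    return pca.fit_transform(X)
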