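"""Core data model for a widefield calcium recording session.

A :class:`Session` bundles the area-level neural matrix (areas x frames at
``fps_neural``), the behavioral :class:`EventTable` (lever pulls, licks, paw
movement initiations, in seconds from session start), optional body-part
position tracks at video rate, and free-form metadata.

Time convention used throughout the package: event times are float seconds;
frame ``i`` corresponds to time ``i / fps``; peri-event time ``t = 0`` is the
event; windows are half-open ``[t_start, t_end)`` in frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Behavioral event kinds recognised by the pipeline.
EVENT_KINDS = ("lever_rewarded", "lever_unrewarded", "lick", "left_paw", "right_paw")

#: Body-part features recognised in tracks.
TRACK_FEATURES = ("left_paw", "right_paw", "jaw", "nose", "ear", "tongue", "lever")

#: Default bilateral area labels (atlas-aligned component names).
DEFAULT_AREA_LABELS = tuple(
    f"{area}_{hemi}"
    for area in ("retrosplenial", "barrel", "limb", "visual", "motor")
    for hemi in ("L", "R")
)

#: Event kinds that correspond to lever interactions.
LEVER_KINDS = ("lever_rewarded", "lever_unrewarded")

#: Event kinds that correspond to tracked body movements.
BODY_KINDS = ("lick", "left_paw", "right_paw")


class EventTable:
    """Table of behavioral events: rows of ``(time_s, kind)`` plus metadata.

    Parameters
    ----------
    data : mapping of kind -> times, or DataFrame with columns time_s, kind
    """

    def __init__(self, data=None):
        if data is None:
            df = pd.DataFrame({"time_s": pd.Series(dtype=float),
                               "kind": pd.Series(dtype=object)})
        elif isinstance(data, pd.DataFrame):
            df = data[["time_s", "kind"]].copy()
            df["time_s"] = df["time_s"].astype(float)
        elif isinstance(data, Mapping):
            frames = [
                pd.DataFrame({"time_s": np.asarray(times, dtype=float), "kind": kind})
                for kind, times in data.items()
            ]
            df = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame({"time_s": pd.Series(dtype=float),
                                     "kind": pd.Series(dtype=object)}))
        else:
            raise TypeError("EventTable accepts a DataFrame, a mapping, or None")
        # stable sort keeps within-kind order deterministic
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
        self._df = df
        self.validate()

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def times(self, kind: str) -> np.ndarray:
        """Sorted event times (seconds) for one kind."""
        return self._df.loc[self._df["kind"] == kind, "time_s"].to_numpy()

    def kinds(self) -> list[str]:
        return sorted(self._df["kind"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self._df.equals(other._df)

    def validate(self) -> None:
        t = self._df["time_s"].to_numpy()
        if len(t) and (~np.isfinite(t)).any():
            raise ValidationError("event times must be finite")
        if len(t) and (t < 0).any():
            raise ValidationError("event times must be non-negative")
        unknown = set(self._df["kind"]) - set(EVENT_KINDS)
        if unknown:
            raise ValidationError(f"unknown event kinds: {sorted(unknown)}")


@dataclass
class BodyTrack:
    """Body-part position traces at video rate.

    ``features`` maps a feature name to an ``(n_video_frames, 2)`` array of
    (x, y) pixel positions; all traces must have equal length.
    """

    features: dict[str, np.ndarray]
    fps_video: float = 15.0

    def __post_init__(self):
        self.features = {k: np.asarray(v, dtype=np.float32) for k, v in self.features.items()}
        self.validate()

    @property
    def n_frames(self) -> int:
        return next(iter(self.features.values())).shape[0] if self.features else 0

    def validate(self) -> None:
        if self.fps_video <= 0:
            raise ValidationError("fps_video must be positive")
        lengths = set()
        for name, arr in self.features.items():
            if name not in TRACK_FEATURES:
                raise ValidationError(f"unknown track feature {name!r}")
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValidationError(f"track {name!r} must have shape (n, 2)")
            if not np.isfinite(arr).all():
                raise ValidationError(f"track {name!r} contains non-finite positions")
            lengths.add(arr.shape[0])
        if len(lengths) > 1:
            raise ValidationError("all track features must have equal length")

    def __eq__(self, other) -> bool:
        if not isinstance(other, BodyTrack):
            return NotImplemented
        if self.fps_video != other.fps_video:
            return False
        if set(self.features) != set(other.features):
            return False
        return all(np.array_equal(self.features[k], other.features[k]) for k in self.features)


@dataclass
class Session:
    """One recording session.

    Attributes
    ----------
    neural : (n_areas, n_frames) float array of fluorescence or dF/F (a.u.)
    fps_neural : imaging rate in Hz (30 by default)
    area_labels : unique names of the area-level components
    events : behavioral EventTable (times in seconds from session start)
    tracks : optional BodyTrack
    session_id : free-form identifier
    session_index : ordinal day for longitudinal trends
    meta : free-form JSON-serializable key/value metadata
    """

    neural: np.ndarray
    fps_neural: float = 30.0
    area_labels: Sequence[str] = DEFAULT_AREA_LABELS
    events: EventTable = field(default_factory=EventTable)
    tracks: BodyTrack | None = None
    session_id: str = "session"
    session_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.neural = np.asarray(self.neural, dtype=np.float32)
        self.area_labels = list(self.area_labels)
        self.validate()

    @property
    def n_areas(self) -> int:
        return self.neural.shape[0]

    @property
    def n_frames(self) -> int:
        return self.neural.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps_neural

    def area_index(self, label: str) -> int:
        try:
            return self.area_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown area label {label!r}") from None

    def validate(self) -> None:
        if self.neural.ndim != 2:
            raise ValidationError("neural must be a 2-D (areas x frames) matrix")
        if self.fps_neural <= 0:
            raise ValidationError("fps_neural must be positive")
        if len(self.area_labels) != self.n_areas:
            raise ValidationError("area_labels length must match neural rows")
        if len(set(self.area_labels)) != len(self.area_labels):
            raise ValidationError("area_labels must be unique")
        t = self.events.df["time_s"].to_numpy()
        if len(t) and (t >= self.duration_s).any():
            raise ValidationError("all event times must fall within [0, duration_s)")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            np.array_equal(self.neural, other.neural)
            and self.fps_neural == other.fps_neural
            and self.area_labels == other.area_labels
            and self.events == other.events
            and self.tracks == other.tracks
            and self.session_id == other.session_id
            and self.session_index == other.session_index
            and self.meta == other.meta
        )


@dataclass
class PipelineConfig:
    """Bundle of analysis parameters shared across pipeline stages."""

    window_s: tuple[float, float] = (-15.0, 15.0)
    feature_window_s: float = 1.0
    folds: int = 10
    alpha: float = 0.05
    lockout_s: float = 3.0
    band_hz: tuple[float, float] = (0.1, 6.0)
    lowpass_hz: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (self.window_s[0] < 0 < self.window_s[1]):
            raise ValidationError("window_s must straddle 0: window_s[0] < 0 < window_s[1]")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
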