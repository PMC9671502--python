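"""On-disk container for sessions.

HDF5 layout::

    /neural/data      (n_areas, n_frames) float32; attrs: fps, area_labels
    /events/<kind>    float64 seconds
    /tracks/<feature> (n_video_frames, 2) float32; group attr: fps
    /meta             attrs: session_id, session_index, json (free-form metadata)

A directory fallback (``neural.npy`` + ``events.csv`` + ``session.json``) is
accepted by :func:`read_session` for array + CSV interchange. Event CSV files
have the two columns ``time_s,kind`` (header required, UTF-8, '.' decimal).

Metadata must be JSON-serializable; it is stored canonically (sorted keys) so
that writing the same session twice produces identical containers apart from
HDF5-internal timestamps (which are disabled where h5py allows).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .session import BodyTrack, EventTable, Session

__all__ = ["read_session", "write_session", "read_events_csv", "write_events_csv"]


def write_events_csv(events: EventTable, path) -> None:
    # %.17g round-trips float64 exactly: I/O must never rescale event times
    events.df.to_csv(path, index=False, columns=["time_s", "kind"],
                     float_format="%.17g")


def read_events_csv(path) -> EventTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_s", "kind"} - set(df.columns)
    if missing:
        raise FormatError(f"event CSV missing columns: {sorted(missing)}")
    return EventTable(df)


def write_session(session: Session, path) -> None:
    """Write a session to an HDF5 container readable by :func:`read_session`."""
    session.validate()
    with h5py.File(path, "w") as f:
        g = f.create_group("neural")
        g.create_dataset("data", data=session.neural.astype(np.float32),
                         track_times=False)
        g.attrs["fps"] = float(session.fps_neural)
        g.attrs["area_labels"] = [str(a) for a in session.area_labels]

        ge = f.create_group("events")
        for kind in session.events.kinds():
            ge.create_dataset(kind, data=session.events.times(kind).astype(np.float64),
                              track_times=False)

        if session.tracks is not None:
            gt = f.create_group("tracks")
            gt.attrs["fps"] = float(session.tracks.fps_video)
            for name in sorted(session.tracks.features):
                gt.create_dataset(name, data=session.tracks.features[name].astype(np.float32),
                                  track_times=False)

        gm = f.create_group("meta")
        gm.attrs["session_id"] = session.session_id
        gm.attrs["session_index"] = int(session.session_index)
        gm.attrs["json"] = json.dumps(session.meta, sort_keys=True)


def _read_h5(path: Path) -> Session:
    with h5py.File(path, "r") as f:
        if "neural" not in f or "data" not in f["neural"]:
            raise FormatError(f"{path}: missing group /neural/data")
        g = f["neural"]
        neural = np.asarray(g["data"], dtype=np.float32)
        fps = float(g.attrs["fps"])
        area_labels = [a if isinstance(a, str) else a.decode() for a in g.attrs["area_labels"]]

        events = {}
        if "events" in f:
            for kind in f["events"]:
                events[kind] = np.asarray(f["events"][kind], dtype=np.float64)

        tracks = None
        if "tracks" in f:
            gt = f["tracks"]
            feats = {name: np.asarray(gt[name], dtype=np.float32) for name in gt}
            tracks = BodyTrack(features=feats, fps_video=float(gt.attrs["fps"]))

        if "meta" not in f:
            raise FormatError(f"{path}: missing group /meta")
        gm = f["meta"]
        meta = json.loads(gm.attrs.get("json", "{}"))
        session_id = gm.attrs.get("session_id", "session")
        session_index = int(gm.attrs.get("session_index", 0))

    return Session(neural=neural, fps_neural=fps, area_labels=area_labels,
                   events=EventTable(events), tracks=tracks,
                   session_id=str(session_id), session_index=session_index, meta=meta)


def _read_dir(path: Path) -> Session:
    npy = path / "neural.npy"
    if not npy.exists():
        raise FormatError(f"{path}: missing neural.npy array file")
    neural = np.load(npy)
    csv = path / "events.csv"
    events = read_events_csv(csv) if csv.exists() else EventTable()
    info_path = path / "session.json"
    info = json.loads(info_path.read_text()) if info_path.exists() else {}
    return Session(
        neural=neural,
        fps_neural=float(info.get("fps_neural", 30.0)),
        area_labels=info.get("area_labels", [f"area_{i}" for i in range(neural.shape[0])]),
        events=events,
        session_id=info.get("session_id", path.name),
        session_index=int(info.get("session_index", 0)),
        meta=info.get("meta", {}),
    )


def read_session(path) -> Session:
    """Read a session container (HDF5 file or array+CSV directory)."""
    path = Path(path)
    if path.is_dir():
        return _read_dir(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_h5(path)
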