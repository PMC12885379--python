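"""Shared domain containers used across assay modules.

Coordinate convention: analysis frame has +y pointing dorsally and all
positions in micrometres. Frame indices are 1-based everywhere (schedules,
traces, tracks); loaders are responsible for any conversion from
image-convention coordinates or 0-based exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("growth_cone", "glial_nucleus", "drg_dorsal_border", "head", "centroid")


@dataclass
class ObjectTrack:
    """Time-stamped x,y positions (µm) of one labeled object."""

    object_id: str
    role: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x and y must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    def has_frame(self, frame: int) -> bool:
        return bool(np.isin(frame, self.frames))

    def index_of(self, frame: int) -> int:
        idx = np.searchsorted(self.frames, frame)
        if idx >= len(self.frames) or self.frames[idx] != frame:
            raise KeyError(f"track {self.object_id!r} has no frame {frame}")
        return int(idx)

    def position_at(self, frame: int) -> tuple[float, float]:
        i = self.index_of(frame)
        return float(self.x[i]), float(self.y[i])

    def to_frame_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "object_id": self.object_id,
                "role": self.role,
                "frame": self.frames,
                "x_um": self.x,
                "y_um": self.y,
            }
        )


def tracks_to_csv(tracks: list[ObjectTrack], path, header: dict | None = None) -> None:
    """Write tracks as tidy CSV (one row per object per frame).

    Optional ``header`` entries are emitted as leading ``# key=value`` lines.
    """
    table = pd.concat([t.to_frame_table() for t in tracks], ignore_index=True)
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        table.to_csv(fh, index=False)


def read_header_keys(path) -> dict[str, str]:
    """Parse leading ``# key=value`` comment lines of a CSV file."""
    keys: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                keys[k.strip()] = v.strip()
    return keys


def tracks_from_csv(path) -> list[ObjectTrack]:
    table = pd.read_csv(path, comment="#")
    tracks = []
    for (oid, role), sub in table.groupby(["object_id", "role"], sort=False):
        sub = sub.sort_values("frame")
        tracks.append(
            ObjectTrack(str(oid), str(role), sub["frame"].to_numpy(), sub["x_um"].to_numpy(), sub["y_um"].to_numpy())
        )
    return tracks


@dataclass
class GroundTruth:
    """Sidecar describing what a synthetic generator planted."""

    assay: str
    planted: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"assay": self.assay, "planted": _jsonify(self.planted)}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
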