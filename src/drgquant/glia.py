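"""Glial migration metrics from object tracks.

Per-frame dorsal offsets are measured against the DRG dorsal-border track,
the 140-timepoint analysis window is supplied explicitly (never inferred),
and total migration is the Euclidean displacement between the window's
first and last frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ObjectTrack

DEFAULT_N_TIMEPOINTS = 140


@dataclass
class MigrationSummary:
    object_id: str
    mean_dorsal_offset_um: float
    offsets_um: np.ndarray
    total_migration_um: float
    dorsal_migration_um: float
    n_timepoints: int

    def to_dict(self) -> dict:
        return {
            "object_id": self.object_id,
            "mean_dorsal_offset_um": self.mean_dorsal_offset_um,
            "total_migration_um": self.total_migration_um,
            "dorsal_migration_um": self.dorsal_migration_um,
            "n_timepoints": self.n_timepoints,
        }


def _window_indices(track: ObjectTrack, start_frame: int, n_timepoints: int) -> np.ndarray:
    wanted = np.arange(start_frame, start_frame + n_timepoints)
    idx = np.searchsorted(track.frames, wanted)
    ok = (idx < len(track.frames)) & (track.frames[np.minimum(idx, len(track.frames) - 1)] == wanted)
    if not np.all(ok):
        missing = wanted[~ok]
        raise ValueError(
            f"track {track.object_id!r} is missing frames {missing[:10].tolist()}"
            + ("..." if len(missing) > 10 else "")
        )
    return idx


def dorsal_offsets(
    obj: ObjectTrack,
    reference: ObjectTrack,
    start_frame: int,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
) -> np.ndarray:
    """Per-frame dy = y_object − y_reference (positive = dorsal of the border)."""
    oi = _window_indices(obj, start_frame, n_timepoints)
    ri = _window_indices(reference, start_frame, n_timepoints)
    return obj.y[oi] - reference.y[ri]


def select_dorsal_most(
    nuclei: list[ObjectTrack], reference: ObjectTrack, frame: int
) -> str:
    """Id of the nucleus with maximal dorsal offset at ``frame``; ties → smaller id."""
    if not nuclei:
        raise ValueError("no nucleus tracks supplied")
    best_id, best_dy = None, -np.inf
    ref_y = reference.position_at(frame)[1]
    for nuc in sorted(nuclei, key=lambda t: t.object_id):
        if not nuc.has_frame(frame):
            continue
        dy = nuc.position_at(frame)[1] - ref_y
        if dy > best_dy:
            best_id, best_dy = nuc.object_id, dy
    if best_id is None:
        raise ValueError(f"no nucleus track covers frame {frame}")
    return best_id


def total_migration(track: ObjectTrack, t0: int, t140: int) -> float:
    """Euclidean norm of the (x, y) displacement between frames t0 and t140."""
    x0, y0 = track.position_at(t0)
    x1, y1 = track.position_at(t140)
    return float(np.hypot(x1 - x0, y1 - y0))


def dorsal_migration(track: ObjectTrack, t0: int, t140: int) -> float:
    """Signed dorsal (y) component of the t0→t140 displacement."""
    y0 = track.position_at(t0)[1]
    y1 = track.position_at(t140)[1]
    return float(y1 - y0)


def summarize_migration(
    track: ObjectTrack,
    reference: ObjectTrack,
    start_frame: int,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
) -> MigrationSummary:
    offsets = dorsal_offsets(track, reference, start_frame, n_timepoints)
    t_last = start_frame + n_timepoints - 1
    return MigrationSummary(
        object_id=track.object_id,
        mean_dorsal_offset_um=float(np.mean(offsets)),
        offsets_um=offsets,
        total_migration_um=total_migration(track, start_frame, t_last),
        dorsal_migration_um=dorsal_migration(track, start_frame, t_last),
        n_timepoints=n_timepoints,
    )


def target_distances(nuclei_xy: np.ndarray, drg_border_xy) -> np.ndarray:
    """Per-nucleus (dx, dy, r) relative to the DRG dorsal border.

    Suitable for target plots with 5 µm rings; r is the Euclidean distance.
    """
    nuclei_xy = np.atleast_2d(np.asarray(nuclei_xy, dtype=float))
    if nuclei_xy.shape[0] < 1:
        raise ValueError("need at least one nucleus position")
    ref = np.asarray(drg_border_xy, dtype=float)
    d = nuclei_xy - ref
    r = np.hypot(d[:, 0], d[:, 1])
    return np.column_stack([d, r])
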