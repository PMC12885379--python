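"""Cold-evoked shivering quantification from head/centroid tracks.

Shivering is head/tail movement without forward locomotion. The study scored
frames by eye; here an explicit displacement rule stands in: a frame is
shivering when the head moved at least ``move_threshold_um`` since the
previous frame while the net centroid displacement over a centered window
stays at or below ``locomotion_threshold_um``. Both thresholds are exposed
configuration, not inferred values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ObjectTrack, read_header_keys

DEFAULT_MOVE_THRESHOLD_UM = 0.5
DEFAULT_LOCOMOTION_THRESHOLD_UM = 5.0
DEFAULT_WINDOW_FRAMES = 20  # 1 s at 50 ms intervals


@dataclass
class BehaviorRecording:
    head: ObjectTrack
    centroid: ObjectTrack
    interval_ms: float = 50.0
    immersion_frame: int = 1
    analysis_n_frames: int = 400

    def __post_init__(self) -> None:
        if not np.array_equal(self.head.frames, self.centroid.frames):
            raise ValueError("head and centroid tracks must be aligned on frames")
        last_needed = self.immersion_frame + self.analysis_n_frames - 1
        if not (self.head.has_frame(self.immersion_frame) and self.head.has_frame(last_needed)):
            raise ValueError("analysis window not fully within the tracks")

    @property
    def window_seconds(self) -> float:
        """Duration of the analysis window (analysis_n_frames × interval)."""
        return self.analysis_n_frames * self.interval_ms / 1000.0

    @property
    def movie_seconds(self) -> float:
        """Duration spanned by the whole recorded movie."""
        return len(self.head) * self.interval_ms / 1000.0


@dataclass
class ShiverResult:
    shiver_frames: np.ndarray  # boolean, aligned with analysis window frames
    analysis_frames: np.ndarray  # 1-based frame indices of the window
    pct_shivering: float
    mean_head_displacement_per_frame: float

    def to_dict(self) -> dict:
        return {
            "pct_shivering": self.pct_shivering,
            "n_shiver_frames": int(np.sum(self.shiver_frames)),
            "n_analysis_frames": int(len(self.shiver_frames)),
            "mean_head_displacement_per_frame_um": self.mean_head_displacement_per_frame,
        }


def _step_lengths(track: ObjectTrack) -> np.ndarray:
    """Per-frame step length; step[i] is the move into frames[i] (0 for the first)."""
    dx = np.diff(track.x, prepend=track.x[0])
    dy = np.diff(track.y, prepend=track.y[0])
    return np.hypot(dx, dy)


def classify_shiver(
    rec: BehaviorRecording,
    move_threshold_um: float = DEFAULT_MOVE_THRESHOLD_UM,
    locomotion_threshold_um: float = DEFAULT_LOCOMOTION_THRESHOLD_UM,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
) -> ShiverResult:
    """Classify each frame of the analysis window as shivering or not.

    Frame f shivers iff the head step into f is >= move_threshold AND the
    net centroid displacement over the centered window of ``window_frames``
    is <= locomotion_threshold. The percentage denominator is always
    exactly ``analysis_n_frames``.
    """
    if move_threshold_um <= 0 or locomotion_threshold_um <= 0:
        raise ValueError("thresholds must be positive")
    if window_frames % 2 != 0:
        raise ValueError("window_frames must be even (centered window)")

    start = rec.head.index_of(rec.immersion_frame)
    stop = start + rec.analysis_n_frames
    head_steps = _step_lengths(rec.head)
    half = window_frames // 2
    n_track = len(rec.centroid)
    if stop + half > n_track or start - half < 0:
        warnings.warn(
            "locomotion window extends past the track; truncating at track bounds",
            stacklevel=2,
        )

    cx, cy = rec.centroid.x, rec.centroid.y
    idx = np.arange(start, stop)
    lo = np.clip(idx - half, 0, n_track - 1)
    hi = np.clip(idx + half, 0, n_track - 1)
    net = np.hypot(cx[hi] - cx[lo], cy[hi] - cy[lo])

    shiver = (head_steps[idx] >= move_threshold_um) & (net <= locomotion_threshold_um)
    pct = 100.0 * float(np.sum(shiver)) / rec.analysis_n_frames
    return ShiverResult(
        shiver_frames=shiver,
        analysis_frames=rec.head.frames[idx],
        pct_shivering=pct,
        mean_head_displacement_per_frame=float(np.mean(head_steps[idx])),
    )


def head_displacement_summary(rec: BehaviorRecording) -> float:
    """Mean per-frame head step length (µm) over the analysis window."""
    if len(rec.head) < 2:
        raise ValueError("need >=2 frames")
    start = rec.head.index_of(rec.immersion_frame)
    steps = _step_lengths(rec.head)[start : start + rec.analysis_n_frames]
    return float(np.mean(steps))


def compare_conditions(results_23c: list[float], results_4c: list[float]) -> dict:
    """Paired t-test on per-animal head displacement between water conditions."""
    from .stats import paired_ttest

    if len(results_23c) != len(results_4c):
        raise ValueError("conditions must be paired per animal")
    deltas = np.asarray(results_4c, dtype=float) - np.asarray(results_23c, dtype=float)
    result = paired_ttest(results_23c, results_4c)
    return {"test": result, "deltas": deltas, "mean_delta": float(np.mean(deltas))}


# ---------------------------------------------------------------------------
# I/O

def read_behavior_csv(path) -> BehaviorRecording:
    """Columns frame, head_x, head_y, centroid_x, centroid_y; header keys
    interval_ms, immersion_frame[, analysis_n_frames]."""
    keys = read_header_keys(path)
    table = pd.read_csv(path, comment="#").sort_values("frame")
    frames = table["frame"].to_numpy()
    head = ObjectTrack("head", "head", frames, table["head_x"].to_numpy(), table["head_y"].to_numpy())
    centroid = ObjectTrack(
        "centroid", "centroid", frames, table["centroid_x"].to_numpy(), table["centroid_y"].to_numpy()
    )
    return BehaviorRecording(
        head=head,
        centroid=centroid,
        interval_ms=float(keys.get("interval_ms", 50.0)),
        immersion_frame=int(keys.get("immersion_frame", 1)),
        analysis_n_frames=int(keys.get("analysis_n_frames", 400)),
    )


def write_behavior_csv(rec: BehaviorRecording, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# interval_ms={rec.interval_ms}\n")
        fh.write(f"# immersion_frame={rec.immersion_frame}\n")
        fh.write(f"# analysis_n_frames={rec.analysis_n_frames}\n")
        pd.DataFrame(
            {
                "frame": rec.head.frames,
                "head_x": rec.head.x,
                "head_y": rec.head.y,
                "centroid_x": rec.centroid.x,
                "centroid_y": rec.centroid.y,
            }
        ).to_csv(fh, index=False)
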