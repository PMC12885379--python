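"""Stimulus-locked calcium activity scoring.

Each cell's trace is standardized against its own full-timelapse mean and
sample standard deviation; a z-score of 2.0 or more is an activation event.
Cells are classified against the water schedule: active at the first
cold-water frame → rapid/synchronous with the DRG, first crossing after it
→ delayed, never crossing → none. Animals are included only when at least
one DRG neuron is rapid.

The z-score baseline defaults to the full trace. ``baseline="pre_stimulus"``
restricts mean/sd to frames before the room-temperature addition instead;
every summary records which baseline was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import read_header_keys

ACTIVATION_Z = 2.0
CATEGORY_RAPID = "rapid_synchronous"
CATEGORY_DELAYED = "delayed"
CATEGORY_NONE = "none"


@dataclass
class CalciumRecording:
    """Cell × frame ROI integrated-density matrix with roles and schedule."""

    cell_ids: list[str]
    roles: list[str]  # per-cell: "drg" | "spinal"
    matrix: np.ndarray
    interval_seconds: float = 5.0
    rt_frame: int = 8
    cold_frame: int = 16
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be cell × frame")
        if len(self.cell_ids) != self.matrix.shape[0] or len(self.roles) != self.matrix.shape[0]:
            raise ValueError("cell_ids/roles must match matrix rows")
        bad = set(self.roles) - {"drg", "spinal"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if not (1 <= self.rt_frame < self.cold_frame <= self.n_frames):
            raise ValueError("schedule must satisfy 1 <= rt_frame < cold_frame <= n_frames")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def duration_seconds(self) -> float:
        """Total scheduled duration of the timelapse."""
        return self.n_frames * self.interval_seconds


@dataclass
class ActivationCall:
    cell_id: str
    category: str
    first_active_frame: int | None
    z_at_cold_frame: float
    rt_responder: bool = False
    unanalyzable: bool = False


@dataclass
class SynchronySummary:
    animal_id: str
    included: bool
    drg_rapid_count: int
    n_spinal_analyzable: int
    n_rapid: int
    n_delayed: int
    n_none: int
    baseline: str = "full_trace"
    calls: list[ActivationCall] = field(default_factory=list)

    @property
    def pct_spinal_rapid(self) -> float:
        return 100.0 * self.n_rapid / self.n_spinal_analyzable

    @property
    def pct_spinal_delayed(self) -> float:
        return 100.0 * self.n_delayed / self.n_spinal_analyzable

    @property
    def pct_spinal_none(self) -> float:
        return 100.0 * self.n_none / self.n_spinal_analyzable

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "included": self.included,
            "drg_rapid_count": self.drg_rapid_count,
            "n_spinal_analyzable": self.n_spinal_analyzable,
            "pct_spinal_rapid": self.pct_spinal_rapid,
            "pct_spinal_delayed": self.pct_spinal_delayed,
            "pct_spinal_none": self.pct_spinal_none,
            "baseline": self.baseline,
        }


def zscore_cells(
    recording: CalciumRecording, baseline: str = "full_trace"
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each cell's trace against its own mean and sample SD.

    Returns (z matrix, unanalyzable mask). Cells with zero variance in the
    baseline get NaN rows and are flagged unanalyzable.
    """
    m = recording.matrix
    if baseline == "full_trace":
        base = m
    elif baseline == "pre_stimulus":
        base = m[:, : recording.rt_frame - 1]
        if base.shape[1] < 2:
            raise ValueError("pre-stimulus baseline needs >=2 frames before rt_frame")
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    mean = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1, keepdims=True)  # sample SD, spreadsheet STDEV
    unanalyzable = (sd == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - mean) / sd
    z[unanalyzable, :] = np.nan
    return z, unanalyzable


def classify_cell(
    zrow: np.ndarray, cold_frame: int, threshold: float = ACTIVATION_Z, cell_id: str = ""
) -> ActivationCall:
    """Categorize one cell's z-trace against the cold-water frame.

    The threshold comparison is inclusive (>= 2.0). Frames before cold_frame
    do not enter the categorization, but a cell whose only crossings are
    pre-cold is flagged rt_responder (the three categories do not cover it).
    """
    zrow = np.asarray(zrow, dtype=float)
    if cold_frame > len(zrow):
        raise ValueError("zrow does not cover cold_frame")
    if np.all(np.isnan(zrow)):
        return ActivationCall(cell_id, CATEGORY_NONE, None, np.nan, unanalyzable=True)
    active = zrow >= threshold
    crossings = np.flatnonzero(active) + 1  # 1-based frames
    first_any = int(crossings[0]) if len(crossings) else None
    z_cold = float(zrow[cold_frame - 1])
    if z_cold >= threshold:
        return ActivationCall(cell_id, CATEGORY_RAPID, cold_frame, z_cold)
    post = crossings[crossings > cold_frame]
    if len(post):
        return ActivationCall(cell_id, CATEGORY_DELAYED, int(post[0]), z_cold)
    rt_only = first_any is not None and first_any < cold_frame
    return ActivationCall(cell_id, CATEGORY_NONE, None, z_cold, rt_responder=rt_only)


def summarize_animal(
    recording: CalciumRecording,
    threshold: float = ACTIVATION_Z,
    baseline: str = "full_trace",
) -> SynchronySummary:
    """Per-animal synchrony summary over analyzable spinal cells."""
    z, unanalyzable = zscore_cells(recording, baseline=baseline)
    calls = [
        classify_cell(z[i], recording.cold_frame, threshold, cell_id=recording.cell_ids[i])
        for i in range(recording.n_cells)
    ]
    roles = np.asarray(recording.roles)
    drg_rapid = sum(
        1
        for i, c in enumerate(calls)
        if roles[i] == "drg" and c.category == CATEGORY_RAPID
    )
    spinal = [c for i, c in enumerate(calls) if roles[i] == "spinal" and not c.unanalyzable]
    if not spinal:
        raise ValueError("no analyzable spinal cells")
    n_rapid = sum(c.category == CATEGORY_RAPID for c in spinal)
    n_delayed = sum(c.category == CATEGORY_DELAYED for c in spinal)
    n_none = sum(c.category == CATEGORY_NONE for c in spinal)
    return SynchronySummary(
        animal_id=recording.animal_id,
        included=drg_rapid >= 1,
        drg_rapid_count=drg_rapid,
        n_spinal_analyzable=len(spinal),
        n_rapid=n_rapid,
        n_delayed=n_delayed,
        n_none=n_none,
        baseline=baseline,
        calls=calls,
    )


def compare_groups(summaries_by_group: dict[str, list[SynchronySummary]]) -> dict:
    """Pairwise two-sided Fisher exact tests on pooled rapid vs delayed counts."""
    from .stats import ContingencyTable2x2, fisher_exact

    if len(summaries_by_group) < 2:
        raise ValueError("need >=2 groups")
    pooled = {}
    for label, summaries in summaries_by_group.items():
        if not summaries:
            raise ValueError(f"group {label!r} is empty")
        pooled[label] = (
            sum(s.n_rapid for s in summaries),
            sum(s.n_delayed for s in summaries),
        )
    results = {}
    labels = sorted(pooled)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            table = ContingencyTable2x2(pooled[a][0], pooled[a][1], pooled[b][0], pooled[b][1])
            results[(a, b)] = fisher_exact(table)
    return results


# ---------------------------------------------------------------------------
# I/O

def read_recording_csv(path) -> CalciumRecording:
    """Read a wide (cell_id, role, f1..fN) or tidy (cell_id, role, frame, value) CSV."""
    keys = read_header_keys(path)
    table = pd.read_csv(path, comment="#")
    if "frame" in table.columns:  # tidy
        wide = table.pivot_table(index=["cell_id", "role"], columns="frame", values="value")
        wide = wide.sort_index(axis=1)
        cell_ids = [str(c) for c, _ in wide.index]
        roles = [str(r) for _, r in wide.index]
        matrix = wide.to_numpy()
    else:
        fcols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
        fcols.sort(key=lambda c: int(c[1:]))
        cell_ids = table["cell_id"].astype(str).tolist()
        roles = table["role"].astype(str).tolist()
        matrix = table[fcols].to_numpy()
    return CalciumRecording(
        cell_ids=cell_ids,
        roles=roles,
        matrix=matrix,
        interval_seconds=float(keys.get("interval_seconds", 5.0)),
        rt_frame=int(keys.get("rt_frame", 8)),
        cold_frame=int(keys.get("cold_frame", 16)),
        animal_id=str(path),
    )


def write_recording_csv(recording: CalciumRecording, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# interval_seconds={recording.interval_seconds}\n")
        fh.write(f"# rt_frame={recording.rt_frame}\n")
        fh.write(f"# cold_frame={recording.cold_frame}\n")
        table = pd.DataFrame(
            recording.matrix, columns=[f"f{i}" for i in range(1, recording.n_frames + 1)]
        )
        table.insert(0, "role", recording.roles)
        table.insert(0, "cell_id", recording.cell_ids)
        table.to_csv(fh, index=False)


def calls_to_frame(calls: list[ActivationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "category": c.category,
                "first_active_frame": c.first_active_frame,
                "z_at_cold_frame": c.z_at_cold_frame,
                "rt_responder": c.rt_responder,
                "unanalyzable": c.unanalyzable,
            }
            for c in calls
        ]
    )
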