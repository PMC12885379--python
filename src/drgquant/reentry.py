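"""Axon re-entry scoring from dual-channel orthogonal line profiles.

An axon is scored *entered* when the peak of its fluorescence along the
8 µm line across the junction lies strictly medial (smaller coordinate)
of the boundary-channel peak, and *not entered* otherwise. Ties and flat
channels score conservatively as not entered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import read_header_keys

DEFAULT_LINE_LENGTH_UM = 8.0


@dataclass
class OrthProfilePair:
    """Co-registered axon and boundary intensities along a medial→lateral line.

    The medial end of the line is coordinate 0; this orientation must be
    declared by the producer of the profile (no auto-detection).
    """

    positions: np.ndarray
    axon_values: np.ndarray
    boundary_values: np.ndarray
    line_length_um: float = DEFAULT_LINE_LENGTH_UM
    record_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.axon_values = np.asarray(self.axon_values, dtype=float)
        self.boundary_values = np.asarray(self.boundary_values, dtype=float)
        n = len(self.positions)
        if n < 3 or len(self.axon_values) != n or len(self.boundary_values) != n:
            raise ValueError("profiles need >=3 co-registered samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def sample_spacing(self) -> float:
        return float(np.median(np.diff(self.positions)))


@dataclass
class EntryCall:
    outcome: str  # "entered" | "not_entered"
    axon_peak_um: float | None
    boundary_peak_um: float | None
    no_peak_flag: bool = False
    record_id: str = ""


@dataclass
class OutcomeGroup:
    label: str
    n_entered: int
    n_failed: int

    @property
    def n(self) -> int:
        return self.n_entered + self.n_failed

    @property
    def pct_entered(self) -> float:
        return 100.0 * self.n_entered / self.n


def locate_peak(values: np.ndarray, positions: np.ndarray, refine: bool = True) -> float | None:
    """Position (µm) of the global intensity maximum along the line.

    Ties break toward the medial (smaller) coordinate. With ``refine``,
    interior maxima get a 3-point parabolic sub-sample correction; maxima
    at either end of the line are left unrefined. An all-constant series
    has no peak and returns None.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(values) < 3:
        raise ValueError("need >=3 samples")
    if np.ptp(values) == 0:
        return None
    i = int(np.argmax(values))  # first occurrence = medial tie-break
    pos = float(positions[i])
    if refine and 0 < i < len(values) - 1:
        y0, y1, y2 = values[i - 1], values[i], values[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper curvature; flat-top gives denom == 0 → no shift
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            spacing = 0.5 * (positions[i + 1] - positions[i - 1])
            pos += delta * spacing
    return pos


def classify_entry(pair: OrthProfilePair, refine: bool = True) -> EntryCall:
    """Entered iff the axon peak is strictly medial of the boundary peak.

    Coincident peaks or a flat channel score not_entered (re-entry is the
    positive claim; ties are scored conservatively).
    """
    axon_peak = locate_peak(pair.axon_values, pair.positions, refine=refine)
    boundary_peak = locate_peak(pair.boundary_values, pair.positions, refine=refine)
    no_peak = axon_peak is None or boundary_peak is None
    entered = (not no_peak) and axon_peak < boundary_peak
    return EntryCall(
        outcome="entered" if entered else "not_entered",
        axon_peak_um=axon_peak,
        boundary_peak_um=boundary_peak,
        no_peak_flag=no_peak,
        record_id=pair.record_id,
    )


def summarize_outcomes(calls: list[EntryCall], label: str) -> OutcomeGroup:
    if not calls:
        raise ValueError("cannot summarize an empty group")
    n_entered = sum(1 for c in calls if c.outcome == "entered")
    return OutcomeGroup(label=label, n_entered=n_entered, n_failed=len(calls) - n_entered)


# ---------------------------------------------------------------------------
# I/O

def read_profile_csv(path) -> OrthProfilePair:
    """Columns position_um, axon, boundary; header keys line_length_um, medial_end."""
    keys = read_header_keys(path)
    medial_end = keys.get("medial_end", "0")
    if medial_end not in {"0", "zero", "start"}:
        raise ValueError(
            "profile files must declare medial_end=0 (medial end at coordinate 0); "
            f"got medial_end={medial_end!r}"
        )
    table = pd.read_csv(path, comment="#").sort_values("position_um")
    return OrthProfilePair(
        positions=table["position_um"].to_numpy(),
        axon_values=table["axon"].to_numpy(),
        boundary_values=table["boundary"].to_numpy(),
        line_length_um=float(keys.get("line_length_um", DEFAULT_LINE_LENGTH_UM)),
        record_id=str(path),
    )


def write_profile_csv(pair: OrthProfilePair, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# line_length_um={pair.line_length_um}\n")
        fh.write("# medial_end=0\n")
        pd.DataFrame(
            {
                "position_um": pair.positions,
                "axon": pair.axon_values,
                "boundary": pair.boundary_values,
            }
        ).to_csv(fh, index=False)


def call_to_dict(call: EntryCall) -> dict:
    return {
        "record_id": call.record_id,
        "outcome": call.outcome,
        "axon_peak_um": call.axon_peak_um,
        "boundary_peak_um": call.boundary_peak_um,
        "no_peak_flag": call.no_peak_flag,
    }


def group_to_dict(group: OutcomeGroup) -> dict:
    return {
        "label": group.label,
        "n_entered": group.n_entered,
        "n_failed": group.n_failed,
        "n": group.n,
        "pct_entered": group.pct_entered,
    }
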