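"""Invadopodia detection from growth-cone actin intensity traces.

The growth-cone signal is background-subtracted frame by frame, thresholded
against its own mean over the analyzed window, and maximal runs of at least
``min_consecutive`` supra-threshold frames become events. Events are binned
into stability classes by duration and compiled per group, overall and
restricted to frames where the growth cone sat at the DREZ.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import read_header_keys

STATE_NAVIGATING = "nav"
STATE_AT_DREZ = "drez"

#: duration bands (minutes, half-open) for the stability classes
TRANSIENT_BAND = (20.0, 40.0)
INTERMEDIATE_BAND = (40.0, 60.0)
STABLE_MIN = 60.0


@dataclass
class IntensityTrace:
    """Per-frame growth-cone integrated density with matched background.

    Frames are 1-based. ``window_start`` marks the first analyzed frame
    (extension onset); the mean threshold and event detection both operate
    on frames >= window_start. ``state`` annotates each frame as
    ``nav`` (navigating) or ``drez`` (growth cone at the DREZ).
    """

    values: np.ndarray
    background: np.ndarray
    interval_minutes: float = 5.0
    window_start: int = 1
    state: np.ndarray | None = None
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("values must be a non-empty 1-D series")
        if len(self.background) != len(self.values):
            raise ValueError(
                f"background length {len(self.background)} != values length {len(self.values)}"
            )
        if self.interval_minutes <= 0:
            raise ValueError("interval_minutes must be positive")
        if not (1 <= self.window_start <= len(self.values)):
            raise ValueError("window_start outside trace")
        if self.state is not None:
            self.state = np.asarray(self.state, dtype=object)
            if len(self.state) != len(self.values):
                raise ValueError("state annotation length mismatch")
            bad = set(self.state) - {STATE_NAVIGATING, STATE_AT_DREZ}
            if bad:
                raise ValueError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def frames(self) -> np.ndarray:
        return np.arange(1, self.n_frames + 1)


@dataclass
class InvadopodiaEvent:
    start_frame: int
    end_frame: int
    duration_minutes: float
    stability_class: str | None = None
    at_drez: bool | None = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class EventCompilation:
    group_label: str
    durations_all: list[float] = field(default_factory=list)
    durations_at_drez: list[float] = field(default_factory=list)
    per_trace_mean_at_drez: list[float] = field(default_factory=list)
    events_by_trace: list[list[InvadopodiaEvent]] = field(default_factory=list)


def background_subtract(trace: IntensityTrace) -> np.ndarray:
    """Per-frame value minus its matched background; negatives preserved."""
    if len(trace.background) != len(trace.values):
        raise ValueError("background length mismatch")
    return trace.values - trace.background


def mean_threshold(corrected: np.ndarray, window_start: int = 1) -> float:
    """Arithmetic mean of the corrected signal over frames >= window_start."""
    corrected = np.asarray(corrected, dtype=float)
    if not (1 <= window_start <= len(corrected)):
        raise ValueError("empty analysis window")
    return float(np.mean(corrected[window_start - 1 :]))


def detect_events(
    corrected: np.ndarray,
    threshold: float,
    interval_minutes: float = 5.0,
    min_consecutive: int = 4,
    first_frame: int = 1,
) -> list[InvadopodiaEvent]:
    """Maximal runs of frames strictly above ``threshold``.

    Runs of length >= min_consecutive become events; duration is
    run length × interval. Runs touching either end of the series count.
    ``first_frame`` gives the 1-based frame index of corrected[0].
    """
    corrected = np.asarray(corrected, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = corrected > threshold  # strict: a frame exactly at the mean does not count
    events: list[InvadopodiaEvent] = []
    padded = np.concatenate(([False], above, [False]))
    diffs = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(diffs[::2], diffs[1::2]):
        length = stop - start
        if length >= min_consecutive:
            events.append(
                InvadopodiaEvent(
                    start_frame=int(start + first_frame),
                    end_frame=int(stop - 1 + first_frame),
                    duration_minutes=float(length * interval_minutes),
                )
            )
    return events


def classify_event(duration_minutes: float) -> str:
    """Stability class from event duration: transient < intermediate < stable.

    Bands are half-open so every achievable duration >= 20 min gets exactly
    one class at any sampling interval: transient [20, 40), intermediate
    [40, 60), stable [60, inf).
    """
    if duration_minutes < TRANSIENT_BAND[0]:
        raise ValueError(f"duration {duration_minutes} min is below the 20 min event minimum")
    if duration_minutes < TRANSIENT_BAND[1]:
        return "transient"
    if duration_minutes < INTERMEDIATE_BAND[1]:
        return "intermediate"
    return "stable"


def analyze_trace(trace: IntensityTrace, min_consecutive: int = 4) -> list[InvadopodiaEvent]:
    """Full single-trace pipeline: subtract, threshold, detect, classify.

    At-DREZ assignment (when the trace is annotated) uses a strict majority
    of the event's frames.
    """
    corrected = background_subtract(trace)
    window = corrected[trace.window_start - 1 :]
    threshold = mean_threshold(corrected, trace.window_start)
    events = detect_events(
        window,
        threshold,
        interval_minutes=trace.interval_minutes,
        min_consecutive=min_consecutive,
        first_frame=trace.window_start,
    )
    for ev in events:
        ev.stability_class = classify_event(ev.duration_minutes)
        if trace.state is not None:
            ev.at_drez = _majority_at_drez(trace, ev)
    return events


def _majority_at_drez(trace: IntensityTrace, event: InvadopodiaEvent) -> bool:
    states = trace.state[event.start_frame - 1 : event.end_frame]
    n_drez = int(np.sum(states == STATE_AT_DREZ))
    return n_drez * 2 > event.n_frames


def compile_events(
    traces: list[IntensityTrace], group_label: str, min_consecutive: int = 4
) -> EventCompilation:
    """Pool event durations across a treatment/genotype group.

    Emits all durations, at-DREZ durations, and per-trace mean at-DREZ
    duration (traces without at-DREZ events contribute no per-trace mean).
    """
    comp = EventCompilation(group_label=group_label)
    for trace in traces:
        if trace.state is None:
            raise ValueError(
                f"trace {trace.trace_id!r} lacks a state annotation; cannot compile at-DREZ events"
            )
        events = analyze_trace(trace, min_consecutive=min_consecutive)
        comp.events_by_trace.append(events)
        drez_durs = [ev.duration_minutes for ev in events if ev.at_drez]
        comp.durations_all.extend(ev.duration_minutes for ev in events)
        comp.durations_at_drez.extend(drez_durs)
        if drez_durs:
            comp.per_trace_mean_at_drez.append(float(np.mean(drez_durs)))
    return comp


def basal_width(profile: np.ndarray, positions: np.ndarray) -> float | None:
    """Full width at half maximum of the peak in an orthogonal line profile.

    Height is measured above the profile minimum (local background); the
    contiguous region around the global maximum with intensity >= half that
    height is delimited by linear interpolation at the crossings. A flat
    profile has no defined width and returns None.
    """
    profile = np.asarray(profile, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(profile) < 3 or len(profile) != len(positions):
        raise ValueError("need >=3 samples with matching positions")
    lo = float(np.min(profile))
    hi = float(np.max(profile))
    if hi == lo:
        return None
    half = lo + (hi - lo) / 2.0
    ipk = int(np.argmax(profile))

    left = positions[0]
    for i in range(ipk, 0, -1):
        if profile[i - 1] < half:
            frac = (half - profile[i - 1]) / (profile[i] - profile[i - 1])
            left = positions[i - 1] + frac * (positions[i] - positions[i - 1])
            break
    right = positions[-1]
    for i in range(ipk, len(profile) - 1):
        if profile[i + 1] < half:
            frac = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = positions[i] + frac * (positions[i + 1] - positions[i])
            break
    return float(right - left)


# ---------------------------------------------------------------------------
# I/O

def read_trace_csv(path) -> IntensityTrace:
    """Read a trace CSV with columns frame, value, background[, state].

    Header keys ``interval_minutes`` and ``window_start`` may be given as
    leading ``# key=value`` lines.
    """
    keys = read_header_keys(path)
    table = pd.read_csv(path, comment="#").sort_values("frame")
    state = table["state"].to_numpy() if "state" in table.columns else None
    return IntensityTrace(
        values=table["value"].to_numpy(),
        background=table["background"].to_numpy(),
        interval_minutes=float(keys.get("interval_minutes", 5.0)),
        window_start=int(keys.get("window_start", 1)),
        state=state,
        trace_id=str(path),
    )


def write_trace_csv(trace: IntensityTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# interval_minutes={trace.interval_minutes}\n")
        fh.write(f"# window_start={trace.window_start}\n")
        table = pd.DataFrame(
            {"frame": trace.frames, "value": trace.values, "background": trace.background}
        )
        if trace.state is not None:
            table["state"] = trace.state
        table.to_csv(fh, index=False)


def events_to_csv(events: list[InvadopodiaEvent], path=None) -> str:
    table = pd.DataFrame(
        [
            {
                "start": ev.start_frame,
                "end": ev.end_frame,
                "duration_min": ev.duration_minutes,
                "class": ev.stability_class,
                "at_drez": ev.at_drez,
            }
            for ev in events
        ],
        columns=["start", "end", "duration_min", "class", "at_drez"],
    )
    if path is None:
        buf = io.StringIO()
        table.to_csv(buf, index=False)
        return buf.getvalue()
    table.to_csv(path, index=False)
    return str(path)


def compilation_to_dict(comp: EventCompilation) -> dict:
    return {
        "group_label": comp.group_label,
        "n_traces": len(comp.events_by_trace),
        "n_events": len(comp.durations_all),
        "durations_all_min": list(comp.durations_all),
        "durations_at_drez_min": list(comp.durations_at_drez),
        "mean_all_min": float(np.mean(comp.durations_all)) if comp.durations_all else None,
        "mean_at_drez_min": float(np.mean(comp.durations_at_drez)) if comp.durations_at_drez else None,
        "per_trace_mean_at_drez_min": list(comp.per_trace_mean_at_drez),
    }
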