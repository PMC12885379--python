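"""Seeded generators that fabricate every input the pipeline consumes.

Each generator returns the analysis-ready record plus a :class:`GroundTruth`
sidecar describing exactly what was planted, so downstream modules can be
checked for exact recovery at noise 0. Identical seed + spec gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import brentq

from .behavior import BehaviorRecording
from .calcium import CalciumRecording
from .hcr import QuantRegion
from .invadopodia import STATE_AT_DREZ, STATE_NAVIGATING, IntensityTrace
from .reentry import DEFAULT_LINE_LENGTH_UM, OrthProfilePair
from .types import GroundTruth, ObjectTrack

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# LifeAct growth-cone traces


@dataclass
class TraceSpec:
    """Recipe for a growth-cone actin trace with planted supra-threshold events."""

    n_frames: int
    interval_minutes: float = 5.0
    baseline_level: float = 1.0
    events: list[tuple[int, int, float]] = field(default_factory=list)  # (start, n_frames, amplitude)
    noise_sd: float = 0.0
    background_level: float = 10.0
    drez_arrival_frame: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        spans = []
        for start, length, _amp in self.events:
            if start < 1 or start + length - 1 > self.n_frames or length < 1:
                raise ValueError(f"event ({start}, {length}) outside [1, {self.n_frames}]")
            spans.append((start, start + length - 1))
        spans.sort()
        for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError(f"events overlap: frames {s1}..{e0}")


def gen_lifeact_trace(spec: TraceSpec) -> tuple[IntensityTrace, GroundTruth]:
    """Trace = baseline + planted event amplitudes + noise, atop a background.

    With noise 0, the background-subtracted signal exceeds the trace mean
    exactly on the planted frames whenever each event amplitude exceeds the
    event-weighted mean excess (always true for a single shared amplitude;
    a weak event can fall below the mean set by much stronger ones).
    """
    rng = np.random.default_rng(spec.seed)
    signal = np.full(spec.n_frames, spec.baseline_level, dtype=float)
    spans = []
    for start, length, amp in spec.events:
        signal[start - 1 : start - 1 + length] += amp
        spans.append({"start_frame": start, "end_frame": start + length - 1, "amplitude": amp})
    background = np.full(spec.n_frames, spec.background_level, dtype=float)
    values = signal + background
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, spec.n_frames)
        background = background + rng.normal(0.0, spec.noise_sd, spec.n_frames)
    state = None
    if spec.drez_arrival_frame is not None:
        state = np.array(
            [STATE_NAVIGATING] * (spec.drez_arrival_frame - 1)
            + [STATE_AT_DREZ] * (spec.n_frames - spec.drez_arrival_frame + 1),
            dtype=object,
        )
    trace = IntensityTrace(
        values=values,
        background=background,
        interval_minutes=spec.interval_minutes,
        window_start=1,
        state=state,
        trace_id=f"synthetic-seed{spec.seed}",
    )
    truth = GroundTruth(
        assay="lifeact_trace",
        planted={
            "events": spans,
            "baseline_level": spec.baseline_level,
            "drez_arrival_frame": spec.drez_arrival_frame,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Orthogonal profiles


def gen_orth_profiles(
    separation_um: float,
    axon_width_um: float = 2.0,
    boundary_width_um: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    line_length_um: float = DEFAULT_LINE_LENGTH_UM,
    sample_spacing_um: float = 0.25,
) -> tuple[OrthProfilePair, GroundTruth]:
    """Two unimodal (Gaussian) profiles on a shared medial→lateral axis.

    The boundary peak sits at the line midpoint; the axon peak at
    midpoint + separation (negative separation = medial). Widths are FWHM.
    """
    if axon_width_um <= 0 or boundary_width_um <= 0:
        raise ValueError("widths must be positive")
    if abs(separation_um) > line_length_um:
        raise ValueError("separation exceeds line length")
    boundary_center = line_length_um / 2.0
    axon_center = boundary_center + separation_um
    if not (0.0 <= axon_center <= line_length_um):
        raise ValueError("separation places the axon peak off the line")
    rng = np.random.default_rng(seed)
    positions = np.arange(0.0, line_length_um + sample_spacing_um / 2, sample_spacing_um)
    axon = np.exp(-0.5 * ((positions - axon_center) / (axon_width_um * FWHM_TO_SIGMA)) ** 2)
    boundary = np.exp(
        -0.5 * ((positions - boundary_center) / (boundary_width_um * FWHM_TO_SIGMA)) ** 2
    )
    if noise_sd > 0:
        axon = axon + rng.normal(0.0, noise_sd, len(positions))
        boundary = boundary + rng.normal(0.0, noise_sd, len(positions))
    pair = OrthProfilePair(positions, axon, boundary, line_length_um=line_length_um)
    truth = GroundTruth(
        assay="orth_profiles",
        planted={
            "axon_center_um": axon_center,
            "boundary_center_um": boundary_center,
            "separation_um": separation_um,
        },
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Object tracks


def gen_tracks(
    n_frames: int,
    drift_um_per_frame: tuple[float, float],
    jitter_sd: float = 0.0,
    start_xy: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    object_id: str = "obj",
    role: str = "glial_nucleus",
) -> tuple[ObjectTrack, GroundTruth]:
    """Linear drift plus Gaussian positional jitter."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    steps = np.arange(n_frames)
    x = start_xy[0] + drift_um_per_frame[0] * steps
    y = start_xy[1] + drift_um_per_frame[1] * steps
    if jitter_sd > 0:
        x = x + rng.normal(0.0, jitter_sd, n_frames)
        y = y + rng.normal(0.0, jitter_sd, n_frames)
    track = ObjectTrack(object_id, role, np.arange(1, n_frames + 1), x, y)
    endpoint = (
        drift_um_per_frame[0] * (n_frames - 1),
        drift_um_per_frame[1] * (n_frames - 1),
    )
    truth = GroundTruth(
        assay="tracks",
        planted={
            "drift_um_per_frame": list(drift_um_per_frame),
            "endpoint_displacement_um": list(endpoint),
            "endpoint_distance_um": float(np.hypot(*endpoint)),
        },
    )
    return track, truth


# ---------------------------------------------------------------------------
# Calcium recordings


@dataclass
class CalciumSpec:
    """Recipe for a GCaMP6s-like recording under the two-water schedule.

    ``responder_classes`` lists one (class, onset_frame) pair per cell —
    DRG cells first, then spinal cells. Onset is ignored for rapid/none
    cells; delayed cells first cross at their onset (>= cold_frame + 1).
    """

    n_drg_cells: int
    n_spinal_cells: int = 30
    n_frames: int = 24
    interval_seconds: float = 5.0
    rt_frame: int = 8
    cold_frame: int = 16
    responder_classes: list[tuple[str, int | None]] = field(default_factory=list)
    rise_frames: int = 2
    decay_per_frame: float = 0.8
    peak_amplitude_sd_units: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.rt_frame < self.cold_frame <= self.n_frames):
            raise ValueError("need rt_frame < cold_frame <= n_frames")
        if not (0.0 < self.decay_per_frame < 1.0):
            raise ValueError("decay fraction must be in (0, 1)")
        n_cells = self.n_drg_cells + self.n_spinal_cells
        if len(self.responder_classes) != n_cells:
            raise ValueError(
                f"responder_classes has {len(self.responder_classes)} entries for {n_cells} cells"
            )
        for cls, onset in self.responder_classes:
            if cls not in {"rapid", "delayed", "none"}:
                raise ValueError(f"unknown responder class {cls!r}")
            if cls == "delayed":
                if onset is None or not (self.cold_frame + 1 <= onset <= self.n_frames):
                    raise ValueError("delayed onset must lie in [cold_frame+1, n_frames]")


def solve_spike_for_z(base: np.ndarray, frame: int, target_z: float) -> float:
    """Value at ``frame`` (1-based) making that frame's full-trace sample
    z-score equal ``target_z``.

    The single-spike z is bounded by (n−1)/√n, so target_z must be below
    that; the base trace must carry some variation elsewhere so that small
    targets are reachable. Solved numerically (the one-spike mean/sd
    equations have no convenient closed form once the base varies).
    """
    base = np.asarray(base, dtype=float)
    n = len(base)
    zmax = (n - 1) / np.sqrt(n)
    if not (-zmax < target_z < zmax):
        raise ValueError(f"target z {target_z} unreachable; |z| < {zmax:.3f} for n = {n}")

    def zscore_of(v: float) -> float:
        trace = base.copy()
        trace[frame - 1] = v
        sd = trace.std(ddof=1)
        if sd == 0:
            return 0.0
        return (v - trace.mean()) / sd

    span = max(np.ptp(base), 1.0)
    lo, hi = base.min() - 1e6 * span, base.max() + 1e6 * span
    return float(brentq(lambda v: zscore_of(v) - target_z, lo, hi, xtol=1e-12))


def gen_calcium(spec: CalciumSpec) -> tuple[CalciumRecording, GroundTruth]:
    """Fabricate per-cell traces matching the planted responder classes.

    Kinetics are a linear rise over ``rise_frames`` then exponential decay —
    a free modelling choice, since only threshold crossings matter
    downstream. The event-peak frame is then solved numerically so the
    cell's full-trace z-score at its peak equals ``peak_amplitude_sd_units``
    exactly (noise 0); rapid cells peak at cold_frame, delayed cells at
    their onset. "none" cells carry a sub-threshold ripple (|z| ≈ 1).
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_drg_cells + spec.n_spinal_cells
    baseline, amp = 100.0, 50.0
    matrix = np.empty((n_cells, spec.n_frames), dtype=float)
    for i, (cls, onset) in enumerate(spec.responder_classes):
        trace = np.full(spec.n_frames, baseline)
        # alternating ripple: gives "none" cells nonzero sd and every cell a varying base
        ripple = np.where(np.arange(spec.n_frames) % 2 == 0, 1.0, -1.0)
        trace += 0.02 * amp * ripple
        if cls in {"rapid", "delayed"}:
            peak_frame = spec.cold_frame if cls == "rapid" else onset
            first_rise = peak_frame - spec.rise_frames + 1
            if cls == "delayed":
                first_rise = max(first_rise, spec.cold_frame + 1)  # keep pre-onset frames quiet
            for k, f in enumerate(range(first_rise, peak_frame + 1)):
                if f >= 1:
                    frac = (k + 1) / (peak_frame - first_rise + 1)
                    trace[f - 1] = baseline + frac * amp
            for f in range(peak_frame + 1, spec.n_frames + 1):
                trace[f - 1] = baseline + amp * spec.decay_per_frame ** (f - peak_frame)
            trace[peak_frame - 1] = solve_spike_for_z(
                trace, peak_frame, spec.peak_amplitude_sd_units
            )
        matrix[i] = trace
    if spec.noise_sd > 0:
        matrix = matrix + rng.normal(0.0, spec.noise_sd, matrix.shape)
    roles = ["drg"] * spec.n_drg_cells + ["spinal"] * spec.n_spinal_cells
    cell_ids = [f"{r}{i + 1}" for i, r in enumerate(roles)]
    recording = CalciumRecording(
        cell_ids=cell_ids,
        roles=roles,
        matrix=matrix,
        interval_seconds=spec.interval_seconds,
        rt_frame=spec.rt_frame,
        cold_frame=spec.cold_frame,
        animal_id=f"synthetic-seed{spec.seed}",
    )
    truth = GroundTruth(
        assay="calcium",
        planted={
            "classes": [
                {"cell_id": cid, "role": role, "class": cls, "onset_frame": onset}
                for cid, role, (cls, onset) in zip(cell_ids, roles, spec.responder_classes)
            ],
            "peak_amplitude_sd_units": spec.peak_amplitude_sd_units,
        },
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Behavior tracks


@dataclass
class BehaviorSpec:
    """Recipe for head/centroid tracks with shiver / swim / still bouts."""

    n_frames: int = 600
    interval_ms: float = 50.0
    bouts: list[tuple[int, int, str, float, float]] = field(default_factory=list)
    # (start_frame, length, kind in {shiver, swim, still}, amplitude_um, net_speed_um_per_frame)
    seed: int = 0

    def __post_init__(self) -> None:
        spans = []
        for start, length, kind, amplitude, _speed in self.bouts:
            if kind not in {"shiver", "swim", "still"}:
                raise ValueError(f"unknown bout kind {kind!r}")
            if amplitude < 0:
                raise ValueError("amplitudes must be >= 0")
            if start < 1 or start + length - 1 > self.n_frames:
                raise ValueError("bout outside recording")
            spans.append((start, start + length - 1))
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError("bouts overlap")


def gen_behavior_tracks(spec: BehaviorSpec) -> tuple[ObjectTrack, ObjectTrack, GroundTruth]:
    """Shiver = head oscillation (sinusoid, 2 frames per half-cycle) with a
    stationary centroid; swim = correlated head+centroid drift; still = rest.
    """
    frames = np.arange(1, spec.n_frames + 1)
    head_x = np.zeros(spec.n_frames)
    head_y = np.zeros(spec.n_frames)
    cent_x = np.zeros(spec.n_frames)
    cent_y = np.zeros(spec.n_frames)
    shiver_frames: list[int] = []
    # swim drift accumulates: carry the running positions forward
    x_off = y_off = 0.0
    cursor = 1
    bouts = sorted(spec.bouts)
    for start, length, kind, amplitude, speed in bouts:
        for f in range(cursor, start):
            head_x[f - 1] = cent_x[f - 1] = x_off
        end = start + length - 1
        for k, f in enumerate(range(start, end + 1)):
            if kind == "shiver":
                head_x[f - 1] = x_off
                head_y[f - 1] = amplitude * np.sin(2.0 * np.pi * k / 4.0)  # half-cycle = 2 frames
                cent_x[f - 1] = x_off
                shiver_frames.append(f)
            elif kind == "swim":
                x_off += speed
                head_x[f - 1] = cent_x[f - 1] = x_off
            else:  # still
                head_x[f - 1] = cent_x[f - 1] = x_off
        cursor = end + 1
    for f in range(cursor, spec.n_frames + 1):
        head_x[f - 1] = cent_x[f - 1] = x_off
    head = ObjectTrack("head", "head", frames, head_x, head_y)
    centroid = ObjectTrack("centroid", "centroid", frames, cent_x, cent_y)
    truth = GroundTruth(
        assay="behavior",
        planted={
            "shiver_frames": shiver_frames,
            "bouts": [
                {"start": s, "length": n, "kind": k, "amplitude_um": a, "net_speed": v}
                for s, n, k, a, v in bouts
            ],
        },
    )
    return head, centroid, truth


def behavior_recording(
    spec: BehaviorSpec, immersion_frame: int = 1, analysis_n_frames: int = 400
) -> tuple[BehaviorRecording, GroundTruth]:
    head, centroid, truth = gen_behavior_tracks(spec)
    rec = BehaviorRecording(
        head=head,
        centroid=centroid,
        interval_ms=spec.interval_ms,
        immersion_frame=immersion_frame,
        analysis_n_frames=analysis_n_frames,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# HCR images


def gen_hcr_image(
    n_puncta: int,
    region_mask: QuantRegion,
    punctum_sigma_um: float = 0.3,
    punctum_peak: float = 500.0,
    background: float = 100.0,
    poisson_noise: bool = False,
    seed: int = 0,
    pixel_size_um: float = 0.1,
    margin_um: float = 2.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """2-D image of well-separated Gaussian puncta on a flat background.

    Centers are sampled uniformly inside the mask polygon subject to a
    pairwise separation of >= 3 sigma; an overcrowded mask is rejected.
    Returns the image and the truth table of planted centers (µm).
    """
    rng = np.random.default_rng(seed)
    poly = region_mask.polygon()
    minx, miny, maxx, maxy = poly.bounds
    centers: list[tuple[float, float]] = []
    min_sep = 3.0 * punctum_sigma_um
    attempts = 0
    max_attempts = 2000 * max(n_puncta, 1)
    while len(centers) < n_puncta:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"mask too small to place {n_puncta} puncta at >= {min_sep:.2f} µm separation"
            )
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not shapely.covers(poly, shapely.Point(x, y)):
            continue
        if any(np.hypot(x - cx, y - cy) < min_sep for cx, cy in centers):
            continue
        centers.append((x, y))

    width = int(np.ceil((maxx + margin_um) / pixel_size_um))
    height = int(np.ceil((maxy + margin_um) / pixel_size_um))
    yy, xx = np.mgrid[0:height, 0:width]
    xs = (xx + 0.5) * pixel_size_um
    ys = (yy + 0.5) * pixel_size_um
    image = np.full((height, width), float(background))
    for cx, cy in centers:
        image += punctum_peak * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * punctum_sigma_um**2)
        )
    if poisson_noise:
        image = rng.poisson(image).astype(float)
    table = pd.DataFrame(centers, columns=["x_um", "y_um"])
    return image, table


# ---------------------------------------------------------------------------
# Orthogonal basal-width profiles (invadopodia vs filopodia)


def gen_width_profile(
    width_um: float,
    line_length_um: float = 8.0,
    sample_spacing_um: float = 0.05,
    peak: float = 100.0,
    baseline: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Gaussian basal profile with planted FWHM = width_um."""
    rng = np.random.default_rng(seed)
    positions = np.arange(0.0, line_length_um + sample_spacing_um / 2, sample_spacing_um)
    sigma = width_um * FWHM_TO_SIGMA
    profile = baseline + peak * np.exp(-0.5 * ((positions - line_length_um / 2) / sigma) ** 2)
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, len(positions))
    truth = GroundTruth(assay="width_profile", planted={"fwhm_um": width_um})
    return profile, positions, truth
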