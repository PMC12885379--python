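"""HCR signal quantification: puncta density and mean-grey measurements.

Images are 2-D intensity arrays with a known pixel size; regions are simple
polygons in µm. Pixels belong to a polygon when their centers are covered
by it (boundary centers count as inside), which mirrors rasterized-ROI
behavior and is deterministic.

The paper's puncta were counted manually; ``detect_puncta`` is an explicit
stand-in (Gaussian smoothing, robust threshold, local maxima) and a
pre-counted puncta table can be supplied instead via ``density_from_table``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from skimage.feature import peak_local_max

DEFAULT_FLOORPLATE_BOX_UM2 = 200.0

REGION_KINDS = ("drg_mask", "dorsal_trace", "background_patch", "floorplate_box")


@dataclass
class QuantRegion:
    """Simple polygon in µm coordinates."""

    vertices_um: np.ndarray
    kind: str = "drg_mask"

    def __post_init__(self) -> None:
        self.vertices_um = np.asarray(self.vertices_um, dtype=float)
        if self.vertices_um.ndim != 2 or self.vertices_um.shape[0] < 3:
            raise ValueError("polygon needs >=3 vertices")
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        poly = shapely.Polygon(self.vertices_um)
        if not poly.is_simple or poly.area <= 0:
            raise ValueError("region must be a simple polygon with positive area")
        self._poly = poly

    @property
    def area_um2(self) -> float:
        return float(self._poly.area)

    def polygon(self) -> shapely.Polygon:
        return self._poly

    def pixel_mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Boolean mask of pixels whose centers the polygon covers.

        Image axis 0 is y, axis 1 is x; pixel (r, c) has its center at
        ((c + 0.5) · ps, (r + 0.5) · ps) in µm.
        """
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        xs = (cols.ravel() + 0.5) * pixel_size_um
        ys = (rows.ravel() + 0.5) * pixel_size_um
        pts = shapely.points(xs, ys)
        covered = shapely.covers(self._poly, pts)
        return covered.reshape(shape)

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float, kind: str = "drg_mask") -> "QuantRegion":
        return cls(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]), kind=kind)


@dataclass
class PunctaResult:
    n_puncta: int
    density_per_um2: float
    centers_um: np.ndarray
    area_um2: float


def detect_puncta(
    image: np.ndarray,
    mask: QuantRegion,
    pixel_size_um: float,
    smooth_sigma_um: float,
    k_sd: float = 3.0,
) -> PunctaResult:
    """Detect bright puncta inside a polygon mask.

    The image is Gaussian-smoothed at ``smooth_sigma_um``; candidates are
    local maxima inside the mask whose smoothed intensity exceeds the masked
    median plus ``k_sd`` robust standard deviations (1.4826 × MAD). Maxima
    closer than 2 sigma are merged by the minimum-distance rule.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    pix = mask.pixel_mask(image.shape, pixel_size_um)
    if not pix.any():
        raise ValueError("mask covers no pixels")
    sigma_px = smooth_sigma_um / pixel_size_um
    smoothed = ndimage.gaussian_filter(image, sigma=sigma_px)
    vals = smoothed[pix]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    thr = med + k_sd * 1.4826 * mad
    min_dist = max(1, int(round(2 * sigma_px)))
    coords = peak_local_max(
        smoothed,
        min_distance=min_dist,
        threshold_abs=np.nextafter(thr, np.inf),  # strictly above threshold
        labels=pix.astype(np.uint8),
        exclude_border=False,
    )
    centers = np.column_stack(
        [(coords[:, 1] + 0.5) * pixel_size_um, (coords[:, 0] + 0.5) * pixel_size_um]
    ) if len(coords) else np.empty((0, 2))
    return PunctaResult(
        n_puncta=len(coords),
        density_per_um2=len(coords) / mask.area_um2,
        centers_um=centers,
        area_um2=mask.area_um2,
    )


def density_from_table(puncta: pd.DataFrame, mask: QuantRegion) -> PunctaResult:
    """Density from a pre-counted puncta table (columns x_um, y_um).

    Only puncta whose coordinates the polygon covers are counted, so the
    manual-count workflow maps directly.
    """
    pts = shapely.points(puncta["x_um"].to_numpy(), puncta["y_um"].to_numpy())
    inside = shapely.covers(mask.polygon(), pts)
    centers = puncta.loc[inside, ["x_um", "y_um"]].to_numpy()
    return PunctaResult(
        n_puncta=int(inside.sum()),
        density_per_um2=float(inside.sum()) / mask.area_um2,
        centers_um=centers,
        area_um2=mask.area_um2,
    )


def corrected_mean_grey(
    image: np.ndarray,
    region: QuantRegion,
    background: QuantRegion,
    pixel_size_um: float,
) -> dict:
    """Mean grey of a region minus an adjacent background region's mean grey.

    Negative results are preserved. Emits both the per-pixel mean (the
    primary value) and the per-µm² variant, since the area convention for
    "intensity divided by area" is ambiguous.
    """
    image = np.asarray(image, dtype=float)
    rmask = region.pixel_mask(image.shape, pixel_size_um)
    bmask = background.pixel_mask(image.shape, pixel_size_um)
    if not rmask.any() or not bmask.any():
        raise ValueError("region or background covers no pixels")
    if (rmask & bmask).any():
        raise ValueError("region and background regions overlap")
    px_area = pixel_size_um**2
    region_mean = float(image[rmask].mean())
    bg_mean = float(image[bmask].mean())
    region_per_um2 = float(image[rmask].sum()) / (rmask.sum() * px_area)
    bg_per_um2 = float(image[bmask].sum()) / (bmask.sum() * px_area)
    return {
        "corrected_mean_grey": region_mean - bg_mean,
        "region_mean_grey": region_mean,
        "background_mean_grey": bg_mean,
        "corrected_mean_per_um2": region_per_um2 - bg_per_um2,
    }


def floorplate_mean(
    image: np.ndarray,
    box_center_um: tuple[float, float],
    pixel_size_um: float,
    box_area_um2: float = DEFAULT_FLOORPLATE_BOX_UM2,
) -> float:
    """Mean grey within an axis-aligned square box of the given area."""
    image = np.asarray(image, dtype=float)
    side = float(np.sqrt(box_area_um2))
    cx, cy = box_center_um
    x0, x1 = cx - side / 2, cx + side / 2
    y0, y1 = cy - side / 2, cy + side / 2
    h, w = image.shape
    if x0 < 0 or y0 < 0 or x1 > w * pixel_size_um or y1 > h * pixel_size_um:
        raise ValueError("box exceeds image bounds")
    box = QuantRegion.rectangle(x0, y0, x1, y1, kind="floorplate_box")
    mask = box.pixel_mask(image.shape, pixel_size_um)
    return float(image[mask].mean())


# ---------------------------------------------------------------------------
# I/O

def read_region_json(obj: dict) -> QuantRegion:
    """GeoJSON-style polygon: {"kind": ..., "coordinates_um": [[x, y], ...]}."""
    return QuantRegion(np.asarray(obj["coordinates_um"], dtype=float), kind=obj.get("kind", "drg_mask"))


def region_to_json(region: QuantRegion) -> dict:
    return {"kind": region.kind, "coordinates_um": region.vertices_um.tolist()}
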