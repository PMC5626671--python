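"""Semi-quantitative SPECT/planar measurements.

ROI/VOI statistics and the ratio metrics used throughout the phantom
analyses: hot-rod-to-background ratio HBR = Hr/BKG and contrast-to-noise
ratio CNR = (Hr - BKG)/SD on the cylinder phantom; sphere-to-background
ratio SBR and the sphere-1/sphere-2 uptake ratio on the body phantom;
lesion-to-background ratio LBR on synthetic lesions; isocontour-VOI
threshold calibration against the known sphere volume; and the
concentration-vs-counts linearity fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .phantoms import GeometryError, VoxelGrid
from .projection import PlanarImage

__all__ = [
    "DegenerateRegionError",
    "RoiSpec",
    "MetricSet",
    "LbrResult",
    "LinearityResult",
    "roi_stats",
    "roi_mask",
    "hot_metrics",
    "isocontour_voi",
    "calibrate_threshold",
    "sbr",
    "uptake_ratio",
    "lbr",
    "linearity",
]


class DegenerateRegionError(ValueError):
    """A region captured no pixels, or a ratio/statistic is undefined."""


@dataclass(frozen=True)
class RoiSpec:
    """A circular (planar / single slice) or spherical (volume) region.

    ``center`` is in mm: (x, z) for a circle on a planar image, (x, y, z)
    for a sphere or for a circle on a volume slice (the slice is the
    transaxial plane nearest the z coordinate unless ``slice_index`` is
    given).
    """

    shape: str  # "circle" | "sphere"
    center: tuple[float, ...]
    diameter_mm: float
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "sphere"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")


def _circle_mask_2d(
    shape: tuple[int, int],
    pixel_size: float,
    origin: np.ndarray,
    center: Sequence[float],
    diameter: float,
) -> np.ndarray:
    cx = origin[0] + (np.arange(shape[0]) + 0.5) * pixel_size
    cz = origin[1] + (np.arange(shape[1]) + 0.5) * pixel_size
    dx = cx[:, None] - center[0]
    dz = cz[None, :] - center[1]
    return dx * dx + dz * dz <= (diameter / 2.0) ** 2


def roi_mask(image: "PlanarImage | VoxelGrid", roi: RoiSpec) -> np.ndarray:
    """Boolean pixel/voxel mask of an ROI (pixel-centre membership)."""
    if isinstance(image, PlanarImage):
        if roi.shape != "circle":
            raise ValueError("planar images take circular ROIs")
        lo = image.origin
        hi = image.origin + np.array(image.values.shape) * image.pixel_size_mm
        r = roi.diameter_mm / 2.0
        if np.any(np.asarray(roi.center) - r < lo) or np.any(
            np.asarray(roi.center) + r > hi
        ):
            raise GeometryError("ROI extends outside the image")
        return _circle_mask_2d(
            image.values.shape, image.pixel_size_mm, image.origin,
            roi.center, roi.diameter_mm,
        )

    grid: VoxelGrid = image
    lo, hi = grid.extent()
    r = roi.diameter_mm / 2.0
    if roi.shape == "sphere":
        c = np.asarray(roi.center, dtype=float)
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise GeometryError("VOI extends outside the volume")
        cx = grid.axis_centers(0)[:, None, None] - c[0]
        cy = grid.axis_centers(1)[None, :, None] - c[1]
        cz = grid.axis_centers(2)[None, None, :] - c[2]
        return cx**2 + cy**2 + cz**2 <= r * r

    # circle on a transaxial (x, y) slice at constant z
    c = np.asarray(roi.center, dtype=float)
    if roi.slice_index is not None:
        k = int(roi.slice_index)
    else:
        k = int(np.argmin(np.abs(grid.axis_centers(2) - c[2])))
    if not 0 <= k < grid.dims[2]:
        raise GeometryError("slice index outside the volume")
    if np.any(c[:2] - r < lo[:2]) or np.any(c[:2] + r > hi[:2]):
        raise GeometryError("ROI extends outside the volume slice")
    cx = grid.axis_centers(0)[:, None] - c[0]
    cy = grid.axis_centers(1)[None, :] - c[1]
    mask = np.zeros(grid.dims, dtype=bool)
    mask[:, :, k] = cx**2 + cy**2 <= r * r
    return mask


def roi_stats(
    image: "PlanarImage | VoxelGrid", roi: RoiSpec
) -> tuple[float, float, int]:
    """(mean, sd, n) over pixels whose centres fall inside the ROI.

    The sd is the sample standard deviation (n - 1 denominator; 0 for a
    single pixel).
    """
    mask = roi_mask(image, roi)
    vals = image.values[mask]
    if vals.size == 0:
        raise DegenerateRegionError("ROI captured no pixel centres")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


@dataclass(frozen=True)
class MetricSet:
    """Cylinder-phantom image-quality metrics for one slice."""

    Hr: float
    BKG: float
    SD: float

    @property
    def HBR(self) -> float:
        return self.Hr / self.BKG

    @property
    def CNR(self) -> float:
        if self.SD == 0:
            raise DegenerateRegionError("CNR undefined: background SD is zero")
        return (self.Hr - self.BKG) / self.SD


def hot_metrics(
    image: "PlanarImage | VoxelGrid",
    rod_roi: RoiSpec,
    background_rois: Sequence[RoiSpec],
) -> MetricSet:
    """Hr = rod-ROI mean; BKG = mean of the background-ROI means;
    SD = sample standard deviation of those means (not pooled pixel sd)."""
    if len(background_rois) < 2:
        raise ValueError("need at least 2 background ROIs")
    hr = roi_stats(image, rod_roi)[0]
    means = np.array([roi_stats(image, r)[0] for r in background_rois])
    bkg = float(means.mean())
    if bkg == 0:
        raise DegenerateRegionError("background mean is zero; ratios undefined")
    sd = float(means.std(ddof=1))
    return MetricSet(Hr=hr, BKG=bkg, SD=sd)


def isocontour_voi(
    volume: VoxelGrid,
    search_region: "RoiSpec | np.ndarray",
    threshold_frac: float,
) -> tuple[np.ndarray, float]:
    """Isocontour VOI: voxels >= threshold_frac * regional maximum,
    restricted to the 6-connected component containing the maximum.

    Returns (mask, volume in cm^3).
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must lie in (0, 1]")
    region = (
        search_region
        if isinstance(search_region, np.ndarray)
        else roi_mask(volume, search_region)
    )
    if not region.any():
        raise DegenerateRegionError("empty search region")
    vals = volume.values
    vmax = vals[region].max()
    if vmax <= 0:
        raise DegenerateRegionError("flat/zero search region; no contour level")
    above = region & (vals >= threshold_frac * vmax)
    labels, _ = ndimage.label(above)  # default structure = 6-connectivity
    peak_idx = np.unravel_index(
        np.argmax(np.where(region, vals, -np.inf)), vals.shape
    )
    mask = labels == labels[peak_idx]
    return mask, float(mask.sum()) * volume.voxel_volume_ml


def calibrate_threshold(
    volume_sets: Mapping[str, Mapping[float, float]],
    true_volume_cm3: float,
    candidates: Sequence[float] = (50.0, 60.0, 70.0, 80.0),
) -> float:
    """Pick the isocontour threshold (percent of maximum) whose measured
    VOI volumes best match the true volume.

    Minimizes the absolute volume error summed across every provided set
    (e.g. one per collimator); ties go to the lower threshold.
    """
    if not volume_sets:
        raise ValueError("no volume tables provided")
    for name, table in volume_sets.items():
        missing = [c for c in candidates if c not in table]
        if missing:
            raise ValueError(f"set {name!r} lacks candidate thresholds {missing}")
    errors = {
        c: sum(abs(table[c] - true_volume_cm3) for table in volume_sets.values())
        for c in candidates
    }
    best = min(sorted(candidates), key=lambda c: (errors[c], c))
    return float(best)


def sbr(
    image: "PlanarImage | VoxelGrid",
    sphere_region: "RoiSpec | np.ndarray",
    background_regions: Sequence[RoiSpec],
) -> float:
    """Sphere-to-background ratio: sphere mean over the mean of the
    background-region means."""
    if isinstance(sphere_region, np.ndarray):
        vals = image.values[sphere_region]
        if vals.size == 0:
            raise DegenerateRegionError("empty sphere region")
        sphere_mean = float(vals.mean())
    else:
        sphere_mean = roi_stats(image, sphere_region)[0]
    means = np.array([roi_stats(image, r)[0] for r in background_regions])
    bkg = float(means.mean())
    if bkg == 0:
        raise DegenerateRegionError("zero background; SBR undefined")
    return sphere_mean / bkg


def uptake_ratio(
    image: "PlanarImage | VoxelGrid",
    region1: "RoiSpec | np.ndarray",
    region2: "RoiSpec | np.ndarray",
    method: str = "roi",
    threshold_frac: float = 0.60,
) -> float:
    """Mean-counts ratio of region 1 to region 2.

    ``method="roi"`` uses the regions directly (planar circular ROIs);
    ``method="isocontour"`` replaces each region by its threshold VOI
    (the SPECT convention).
    """
    def region_mean(region) -> float:
        if method == "isocontour":
            mask, _ = isocontour_voi(image, region, threshold_frac)
            return float(image.values[mask].mean())
        if isinstance(region, np.ndarray):
            vals = image.values[region]
            if vals.size == 0:
                raise DegenerateRegionError("empty region")
            return float(vals.mean())
        return roi_stats(image, region)[0]

    if method not in ("roi", "isocontour"):
        raise ValueError(f"unknown method {method!r}")
    m1, m2 = region_mean(region1), region_mean(region2)
    if m2 == 0:
        raise DegenerateRegionError("zero denominator region; ratio undefined")
    return m1 / m2


@dataclass(frozen=True)
class LbrResult:
    """Per-lesion LBR outcome; ``included`` is False when the lesion fails
    the uptake-inclusion rule (regional max < 2 x reference mean)."""

    included: bool
    value: float | None
    lesion_mean: float | None
    background_mean: float
    voi_volume_cm3: float | None


def lbr(
    volume: VoxelGrid,
    lesion_search_region: "RoiSpec | np.ndarray",
    background_voi: RoiSpec,
    reference_mean: float | None = None,
    threshold_frac: float = 0.60,
    inclusion_factor: float = 2.0,
) -> LbrResult:
    """Lesion-to-background ratio: mean counts in the 60%-isocontour
    lesion VOI over mean counts in the (50 cm^3 spherical) background VOI.

    A lesion is included only if its regional maximum is at least
    ``inclusion_factor`` times the normal-reference mean (default: the
    background VOI mean).
    """
    bkg_mean = roi_stats(volume, background_voi)[0]
    if bkg_mean == 0:
        raise DegenerateRegionError("zero background; LBR undefined")
    ref = bkg_mean if reference_mean is None else reference_mean
    region = (
        lesion_search_region
        if isinstance(lesion_search_region, np.ndarray)
        else roi_mask(volume, lesion_search_region)
    )
    regional_max = float(volume.values[region].max())
    if regional_max < inclusion_factor * ref:
        return LbrResult(False, None, None, bkg_mean, None)
    mask, vol_cm3 = isocontour_voi(volume, region, threshold_frac)
    lesion_mean = float(volume.values[mask].mean())
    return LbrResult(True, lesion_mean / bkg_mean, lesion_mean, bkg_mean, vol_cm3)


@dataclass(frozen=True)
class LinearityResult:
    """OLS fit of reconstructed counts against true concentration."""

    slope: float
    intercept: float
    r: float
    concentrations: tuple[float, ...]
    counts: tuple[float, ...]


def linearity(
    concentrations_kbq_ml: Sequence[float],
    recon_means: Sequence[float],
) -> LinearityResult:
    """Least-squares line through (concentration, reconstructed mean)."""
    x = np.asarray(concentrations_kbq_ml, dtype=float)
    y = np.asarray(recon_means, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched (concentration, counts) points")
    if np.allclose(x, x[0]):
        raise DegenerateRegionError("constant concentrations; fit degenerate")
    fit = stats.linregress(x, y)
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        concentrations=tuple(x),
        counts=tuple(y),
    )
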