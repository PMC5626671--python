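"""Forward projection of voxel phantoms into planar and SPECT count data.

Parallel-beam rotator model: for each view the activity and attenuation
grids are rotated about the scanner (z) axis so the detector faces +y,
then summed along y with Beer-Lambert attenuation and a depth-dependent
Gaussian collimator blur applied slab by slab.  A structureless
septal-penetration/scatter pedestal is added in projection space and
Poisson noise is sampled when a seed is given.

Expected counts per pixel for a voxel of activity a (kBq/mL):
``a * voxel_volume_mL * 1000 * sensitivity(cps/Bq) * t(s) * transmission``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .detection import CollimatorModel, DetectionModel, EnergyWindow, PedestalShape
from .phantoms import GeometryError, VoxelGrid

__all__ = [
    "AcquisitionSpec",
    "PlanarImage",
    "ProjectionSet",
    "project_planar",
    "project_spect",
    "sample_poisson",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and timing.

    SPECT: dual-head system, ``n_views`` frames per detector at
    ``angular_step`` degree steps covering 180 degrees per head (the
    default 30 x 6 deg matches a 30-min scan at 60 s per frame).
    ``seed = None`` yields noiseless expectation images.
    """

    mode: str  # "planar" | "spect"
    matrix: int = 64
    pixel_size_mm: float = 8.8
    n_views: int = 30
    angular_step_deg: float = 6.0
    time_per_view_s: float = 60.0
    orbit_radius_mm: float = 250.0
    collimator: str = "HEGP"
    window: str = "84_20"
    seed: int | None = None
    detector: str = "anterior"  # planar view side: "anterior" | "posterior"

    def __post_init__(self) -> None:
        if self.mode not in ("planar", "spect"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")
        if self.detector not in ("anterior", "posterior"):
            raise ValueError(f"unknown detector side {self.detector!r}")
        if self.time_per_view_s <= 0 or self.pixel_size_mm <= 0:
            raise ValueError("times and pixel sizes must be positive")
        if self.mode == "spect":
            coverage = self.n_views * self.angular_step_deg
            if not np.isclose(coverage, 180.0):
                raise ValueError(
                    "spect acquisition must cover 180 deg per head "
                    f"(got {self.n_views} x {self.angular_step_deg} deg)"
                )

    @property
    def angles_deg(self) -> np.ndarray:
        """All view angles; two heads 180 degrees apart for SPECT."""
        if self.mode == "planar":
            return np.array([0.0])
        head1 = np.arange(self.n_views) * self.angular_step_deg
        return np.concatenate([head1, head1 + 180.0])


@dataclass
class PlanarImage:
    """A 2-D count (or expectation) image with physical pixel geometry.

    ``values[ix, iz]``; ``origin`` is the mm coordinate of the lower
    corner of pixel (0, 0) in the (x, z) detector plane.
    """

    values: np.ndarray
    pixel_size_mm: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("planar image must be 2-D")

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.pixel_size_mm

    def like(self, values: np.ndarray) -> "PlanarImage":
        return PlanarImage(values, self.pixel_size_mm, self.origin.copy())


@dataclass
class ProjectionSet:
    """Angular stack of count images plus acquisition metadata."""

    angles_deg: np.ndarray
    counts: np.ndarray          # (n_views_total, nx, nz)
    spec: AcquisitionSpec
    expectations: np.ndarray | None = None
    pixel_origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.angles_deg):
            raise ValueError("one count image required per view angle")
        if self.spec.seed is not None:
            vals = self.counts
            if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                raise ValueError("count images must hold non-negative integers")

    def view(self, i: int) -> tuple[float, np.ndarray]:
        return float(self.angles_deg[i]), self.counts[i]

    def scaled(self, factor: float) -> "ProjectionSet":
        """Expectation set scaled by a positive factor (noiseless only)."""
        if self.spec.seed is not None:
            raise ValueError("scaling is defined for noiseless expectations")
        return ProjectionSet(
            self.angles_deg.copy(), self.counts * factor, self.spec,
            None if self.expectations is None else self.expectations * factor,
            None if self.pixel_origin is None else self.pixel_origin.copy(),
        )


# ---------------------------------------------------------------------------
# Core rotator
# ---------------------------------------------------------------------------

def _rotate_z(volume: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a volume about the z axis (order-1 spline, no reshape)."""
    if angle_deg % 360.0 == 0.0:
        return volume
    return ndimage.rotate(
        volume, angle_deg, axes=(0, 1), reshape=False, order=1, prefilter=False
    )


def _check_aligned(activity: VoxelGrid, attenuation: VoxelGrid | None) -> None:
    if attenuation is None:
        return
    if (
        activity.dims != attenuation.dims
        or not np.allclose(activity.voxel_size, attenuation.voxel_size)
        or not np.allclose(activity.origin, attenuation.origin)
    ):
        raise GeometryError("activity and attenuation grids are not aligned")


def _project_expectation(
    act: np.ndarray,
    mu: np.ndarray | None,
    voxel_size_mm: float,
    y_centers_mm: np.ndarray,
    sensitivity_cps_per_bq: float,
    time_s: float,
    voxel_volume_ml: float,
    collimator: CollimatorModel | None,
    orbit_radius_mm: float,
    use_blur: bool,
) -> np.ndarray:
    """Noiseless primary expectation image (nx, nz) for the detector at +y."""
    dy_cm = voxel_size_mm / 10.0
    scale = voxel_volume_ml * 1e3 * sensitivity_cps_per_bq * time_s
    if mu is not None:
        # optical depth from each voxel centre to the +y boundary:
        # half of the voxel's own mu plus everything beyond it
        path = np.cumsum(mu[:, ::-1, :], axis=1)[:, ::-1, :] * dy_cm
        trans = np.exp(-(path - 0.5 * mu * dy_cm))
        weighted = act * trans * scale
    else:
        weighted = act * scale

    ny = act.shape[1]
    out = np.zeros((act.shape[0], act.shape[2]))
    if not use_blur or collimator is None:
        return weighted.sum(axis=1)
    depths = orbit_radius_mm - y_centers_mm
    sigmas_px = (
        collimator.fwhm_mm(depths) * _FWHM_TO_SIGMA / voxel_size_mm
    )
    for j in range(ny):
        slab = weighted[:, j, :]
        if slab.any():
            out += ndimage.gaussian_filter(slab, sigmas_px[j], mode="reflect")
    return out


def _add_pedestal(
    primary: np.ndarray,
    source: np.ndarray,
    bg_fraction: float,
    pedestal: PedestalShape,
    pixel_size_mm: float,
) -> np.ndarray:
    """Primary + pedestal.

    The pedestal originates from high-energy photons penetrating the
    septa, which are barely attenuated by the body, so its spatial source
    is the *unattenuated* projection ``source``: a broad Gaussian of it
    plus a flat floor, with total ``source_total * bf / (1 - bf)`` (in
    air, where source == primary, this reproduces the vial
    total-sensitivity split).
    """
    if bg_fraction <= 0:
        return primary
    amount = bg_fraction / (1.0 - bg_fraction)
    sigma_px = pedestal.gaussian_fwhm_mm * _FWHM_TO_SIGMA / pixel_size_mm
    broad = ndimage.gaussian_filter(source, sigma_px, mode="reflect")
    flat = np.full_like(source, source.mean())
    ped = amount * (
        (1.0 - pedestal.flat_weight) * broad + pedestal.flat_weight * flat
    )
    return primary + ped


def sample_poisson(expectation: np.ndarray, seed: int | Sequence[int]) -> np.ndarray:
    """Independent Poisson draws per pixel, reproducible under a fixed seed."""
    expectation = np.asarray(expectation)
    if np.any(expectation < 0):
        raise ValueError("Poisson expectations must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(expectation).astype(np.int64)


# ---------------------------------------------------------------------------
# Public projection operations
# ---------------------------------------------------------------------------

def project_planar(
    activity: VoxelGrid,
    attenuation: VoxelGrid | None,
    spec: AcquisitionSpec,
    model: DetectionModel,
    use_blur: bool = True,
    use_pedestal: bool = True,
) -> PlanarImage:
    """Anteroposterior planar static acquisition (detector anterior, +y).

    Returns counts when ``spec.seed`` is set, else the noiseless
    expectation image.
    """
    _check_aligned(activity, attenuation)
    coll = model.collimator(spec.collimator)
    window = model.window(spec.window)
    bf = coll.bg_fraction(window)
    act_vals = activity.values
    mu_vals = None if attenuation is None else attenuation.values
    if spec.detector == "posterior":
        act_vals = act_vals[:, ::-1, :]
        mu_vals = None if mu_vals is None else mu_vals[:, ::-1, :]
    expectation = _project_expectation(
        act_vals,
        mu_vals,
        float(activity.voxel_size[0]),
        activity.axis_centers(1),
        coll.sensitivity(window) * (1.0 - bf),
        spec.time_per_view_s,
        activity.voxel_volume_ml,
        coll,
        spec.orbit_radius_mm,
        use_blur,
    )
    if use_pedestal:
        scale = (
            activity.voxel_volume_ml * 1e3
            * coll.sensitivity(window) * (1.0 - bf) * spec.time_per_view_s
        )
        source = act_vals.sum(axis=1) * scale
        expectation = _add_pedestal(
            expectation, source, bf, model.pedestal, float(activity.voxel_size[0])
        )
    origin = np.array([activity.origin[0], activity.origin[2]])
    if spec.seed is None:
        return PlanarImage(expectation, float(activity.voxel_size[0]), origin)
    counts = sample_poisson(expectation, [int(spec.seed), 0])
    return PlanarImage(counts, float(activity.voxel_size[0]), origin)


def project_spect(
    activity: VoxelGrid,
    attenuation: VoxelGrid | None,
    spec: AcquisitionSpec,
    model: DetectionModel,
    use_blur: bool = True,
    use_pedestal: bool = True,
) -> ProjectionSet:
    """Dual-head SPECT acquisition: one count image per view angle.

    Each view obeys the planar contract along its own ray direction.  Noise
    streams are derived per view from the master seed
    (``default_rng([seed, view_index])``) so earlier views are unaffected
    by the total view count.
    """
    if spec.mode != "spect":
        raise ValueError("project_spect requires a spect-mode AcquisitionSpec")
    _check_aligned(activity, attenuation)
    coll = model.collimator(spec.collimator)
    window = model.window(spec.window)
    bf = coll.bg_fraction(window)
    mu = None if attenuation is None else attenuation.values
    angles = spec.angles_deg
    y_centers = activity.axis_centers(1)
    expectations = np.empty((len(angles), activity.dims[0], activity.dims[2]))
    for i, angle in enumerate(angles):
        act_r = _rotate_z(activity.values, -angle)
        mu_r = None if mu is None else np.maximum(_rotate_z(mu, -angle), 0.0)
        exp_img = _project_expectation(
            np.maximum(act_r, 0.0),
            mu_r,
            float(activity.voxel_size[0]),
            y_centers,
            coll.sensitivity(window) * (1.0 - bf),
            spec.time_per_view_s,
            activity.voxel_volume_ml,
            coll,
            spec.orbit_radius_mm,
            use_blur,
        )
        if use_pedestal:
            scale = (
                activity.voxel_volume_ml * 1e3
                * coll.sensitivity(window) * (1.0 - bf) * spec.time_per_view_s
            )
            source = np.maximum(act_r, 0.0).sum(axis=1) * scale
            exp_img = _add_pedestal(
                exp_img, source, bf, model.pedestal, float(activity.voxel_size[0])
            )
        expectations[i] = exp_img

    origin = np.array([activity.origin[0], activity.origin[2]])
    if spec.seed is None:
        return ProjectionSet(angles, expectations, spec, expectations, origin)
    counts = np.stack(
        [
            sample_poisson(expectations[i], [int(spec.seed), i])
            for i in range(len(angles))
        ]
    )
    return ProjectionSet(angles, counts, spec, expectations, origin)
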