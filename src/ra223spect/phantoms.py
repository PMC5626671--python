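"""Digital phantoms for Ra-223 SPECT simulation.

Defines geometric primitives with an activity concentration and an
attenuation class, assembles them into the two study phantoms (a water
cylinder with an axial hot rod, and a body phantom with two hot spheres
plus a tube-shaped chamber emulating bowel activity), and rasterizes
them onto regular voxel grids.

Coordinates are right-handed and in millimetres, origin at the phantom
centre: x runs left->right, y posterior->anterior (the anterior detector
sits at +y), z inferior->superior (the scanner axis).  A voxel with index
``i`` spans the half-open interval ``[origin + i*size, origin + (i+1)*size)``
so voxel centres sit at ``origin + (i + 0.5) * size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "Primitive",
    "Phantom",
    "VoxelGrid",
    "LesionCohortSpec",
    "build_cylindrical_phantom",
    "build_body_phantom",
    "voxelize",
    "generate_lesion_cohort",
    "DEFAULT_ATTENUATION",
]


class GeometryError(ValueError):
    """A grid or region does not cover / fit the geometry it must."""


ShapeKind = Literal["sphere", "cylinder", "box"]
AttenuationClass = Literal["water", "contrast_350HU", "air"]

#: Effective linear attenuation coefficients (cm^-1) at the 84-keV window.
#: Per-window values live in the detection-model config; this is the fallback.
DEFAULT_ATTENUATION: dict[str, float] = {
    "water": 0.18,
    "contrast_350HU": 0.21,
    "air": 0.0,
}


@dataclass(frozen=True)
class Primitive:
    """A geometric primitive carrying activity and attenuation.

    Parameters
    ----------
    shape_kind:
        ``"sphere"`` (dimensions = (diameter,)), ``"cylinder"``
        (dimensions = (diameter, height) or (diameter_u, diameter_v, height)
        for an elliptical cross-section) or ``"box"`` (dimensions =
        (dx, dy, dz)).
    center:
        Centre in mm.
    dimensions:
        Shape dimensions in mm, all strictly positive.
    activity_concentration:
        kBq/mL, >= 0.
    attenuation_class:
        One of ``water``, ``contrast_350HU``, ``air``.
    axis:
        Cylinder axis, one of ``"x" | "y" | "z"`` (ignored for other shapes).
    """

    shape_kind: ShapeKind
    center: tuple[float, float, float]
    dimensions: tuple[float, ...]
    activity_concentration: float = 0.0
    attenuation_class: AttenuationClass = "water"
    axis: Literal["x", "y", "z"] = "z"

    def __post_init__(self) -> None:
        if self.shape_kind not in ("sphere", "cylinder", "box"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("all dimensions must be strictly positive")
        if self.activity_concentration < 0:
            raise ValueError("activity_concentration must be >= 0")
        n = len(self.dimensions)
        expected = {"sphere": (1,), "cylinder": (2, 3), "box": (3,)}[self.shape_kind]
        if n not in expected:
            raise ValueError(
                f"{self.shape_kind} expects {expected} dimensions, got {n}"
            )

    # -- geometry ---------------------------------------------------------
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 3) array of mm coordinates."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        if self.shape_kind == "sphere":
            r = self.dimensions[0] / 2.0
            return np.einsum("ij,ij->i", p, p) <= r * r
        if self.shape_kind == "box":
            half = np.asarray(self.dimensions) / 2.0
            return np.all(np.abs(p) <= half, axis=1)
        # cylinder, possibly elliptical cross-section
        ax = "xyz".index(self.axis)
        trans = [i for i in range(3) if i != ax]
        if len(self.dimensions) == 2:
            du = dv = self.dimensions[0]
            height = self.dimensions[1]
        else:
            du, dv, height = self.dimensions
        u = p[:, trans[0]] / (du / 2.0)
        v = p[:, trans[1]] / (dv / 2.0)
        inside_xs = u * u + v * v <= 1.0
        return inside_xs & (np.abs(p[:, ax]) <= height / 2.0)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) mm corners of the axis-aligned bounding box."""
        c = np.asarray(self.center, dtype=float)
        if self.shape_kind == "sphere":
            half = np.full(3, self.dimensions[0] / 2.0)
        elif self.shape_kind == "box":
            half = np.asarray(self.dimensions) / 2.0
        else:
            ax = "xyz".index(self.axis)
            if len(self.dimensions) == 2:
                du = dv = self.dimensions[0]
                height = self.dimensions[1]
            else:
                du, dv, height = self.dimensions
            half = np.empty(3)
            trans = [i for i in range(3) if i != ax]
            half[trans[0]] = du / 2.0
            half[trans[1]] = dv / 2.0
            half[ax] = height / 2.0
        return c - half, c + half

    def volume_ml(self) -> float:
        """Analytic volume in cm^3 (= mL)."""
        if self.shape_kind == "sphere":
            r = self.dimensions[0] / 20.0  # mm -> cm radius
            return 4.0 / 3.0 * np.pi * r**3
        if self.shape_kind == "box":
            return float(np.prod(np.asarray(self.dimensions) / 10.0))
        if len(self.dimensions) == 2:
            du = dv = self.dimensions[0]
            height = self.dimensions[1]
        else:
            du, dv, height = self.dimensions
        return float(np.pi * (du / 20.0) * (dv / 20.0) * (height / 10.0))

    def total_activity_kbq(self) -> float:
        return self.activity_concentration * self.volume_ml()


@dataclass(frozen=True)
class Phantom:
    """An ordered stack of primitives inside a water-filled body outline.

    Later primitives override earlier ones where they overlap; the body
    outline is painted first.
    """

    body_outline: Primitive
    primitives: tuple[Primitive, ...] = ()

    def __post_init__(self) -> None:
        lo_b, hi_b = self.body_outline.bounding_box()
        for prim in self.primitives:
            lo, hi = prim.bounding_box()
            if np.any(lo < lo_b - 1e-9) or np.any(hi > hi_b + 1e-9):
                raise GeometryError(
                    "primitive bounding box extends outside the body outline"
                )

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.body_outline.bounding_box()

    def paint_order(self) -> tuple[Primitive, ...]:
        return (self.body_outline, *self.primitives)


@dataclass
class VoxelGrid:
    """A regular scalar grid with physical spacing.

    ``values`` is indexed ``[ix, iy, iz]``; ``voxel_size`` and ``origin``
    are per-axis mm.  ``values`` may hold activity (kBq/mL), attenuation
    (cm^-1) or counts depending on context.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with dims >= 1")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @classmethod
    def centered(
        cls, dims: Sequence[int], voxel_size: float | Sequence[float]
    ) -> "VoxelGrid":
        dims = tuple(int(d) for d in dims)
        size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        origin = -np.asarray(dims) * size / 2.0
        return cls(np.zeros(dims), size, origin)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size / 10.0))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        upper = self.origin + np.asarray(self.dims) * self.voxel_size
        return self.origin.copy(), upper

    def total_activity_kbq(self) -> float:
        """Only meaningful for activity grids (kBq/mL values)."""
        return float(self.values.sum()) * self.voxel_volume_ml

    def like(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(values, self.voxel_size.copy(), self.origin.copy())


def _sample_offsets(supersample: int, voxel_size: np.ndarray) -> np.ndarray:
    """Sub-voxel centre offsets (s^3, 3) for supersampled rasterization."""
    s = int(supersample)
    frac = (np.arange(s) + 0.5) / s  # in (0, 1)
    ox, oy, oz = np.meshgrid(frac, frac, frac, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    return offs * voxel_size


def voxelize(
    phantom: Phantom,
    grid: VoxelGrid,
    quantity: Literal["activity", "attenuation"] = "activity",
    attenuation_coefficients: dict[str, float] | None = None,
    supersample: int = 1,
) -> VoxelGrid:
    """Rasterize a phantom onto a grid.

    A voxel takes a primitive's value iff its centre lies inside the
    primitive; later primitives override earlier ones.  With
    ``supersample = s > 1`` each voxel is subdivided into ``s^3``
    sub-centres and the painted values are averaged, giving fractional
    partial-volume weights.

    Activity grids carry kBq/mL; attenuation grids carry cm^-1 looked up
    from ``attenuation_coefficients`` by each primitive's class.
    """
    if quantity not in ("activity", "attenuation"):
        raise ValueError(f"unknown quantity {quantity!r}")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    mu = dict(DEFAULT_ATTENUATION)
    if attenuation_coefficients:
        mu.update(attenuation_coefficients)

    lo_g, hi_g = grid.extent()
    lo_p, hi_p = phantom.bounding_box()
    if np.any(lo_p < lo_g - 1e-9) or np.any(hi_p > hi_g + 1e-9):
        raise GeometryError("grid does not cover the phantom bounding box")

    nx, ny, nz = grid.dims
    # voxel lower corners
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    corners = (
        grid.origin
        + np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1) * grid.voxel_size
    )
    offsets = _sample_offsets(supersample, grid.voxel_size)

    accum = np.zeros(corners.shape[0], dtype=float)
    for off in offsets:
        pts = corners + off
        vals = np.zeros(pts.shape[0], dtype=float)
        for prim in phantom.paint_order():
            inside = prim.contains(pts)
            if quantity == "activity":
                vals[inside] = prim.activity_concentration
            else:
                try:
                    vals[inside] = mu[prim.attenuation_class]
                except KeyError:  # pragma: no cover - guarded by Primitive type
                    raise ValueError(
                        f"no attenuation coefficient for {prim.attenuation_class!r}"
                    ) from None
        accum += vals
    accum /= len(offsets)
    return grid.like(accum.reshape(nx, ny, nz))


# ---------------------------------------------------------------------------
# Study phantoms
# ---------------------------------------------------------------------------

def build_cylindrical_phantom(rod_concentration_kbq_ml: float = 2.0) -> Phantom:
    """Water cylinder (diameter 200 mm, height 210 mm) with an axial hot rod
    (diameter 45 mm, height 200 mm) at 2.0 kBq/mL; zero background activity."""
    body = Primitive(
        "cylinder", (0.0, 0.0, 0.0), (200.0, 210.0),
        activity_concentration=0.0, attenuation_class="water", axis="z",
    )
    rod = Primitive(
        "cylinder", (0.0, 0.0, 0.0), (45.0, 200.0),
        activity_concentration=rod_concentration_kbq_ml,
        attenuation_class="water", axis="z",
    )
    return Phantom(body_outline=body, primitives=(rod,))


#: Frozen body-phantom geometry (mm).  The physical phantom's internal
#: layout is not published; this surrogate reproduces the defining feature:
#: the tube chamber overlaps sphere 1 -- and only sphere 1 -- along the
#: anteroposterior projection direction.
BODY_OUTLINE_LR_MM = 300.0
BODY_OUTLINE_AP_MM = 200.0
BODY_OUTLINE_HEIGHT_MM = 210.0
SPHERE_DIAMETER_MM = 28.0
SPHERE_SEPARATION_MM = 80.0
SPHERE1_CENTER = (0.0, 0.0, SPHERE_SEPARATION_MM / 2.0)
SPHERE2_CENTER = (0.0, 0.0, -SPHERE_SEPARATION_MM / 2.0)
TUBE_DIAMETER_MM = 30.0
TUBE_LENGTH_MM = 150.0
TUBE_AP_OFFSET_MM = 60.0  # anterior of sphere 1, centre-to-centre
TUBE_CENTER = (0.0, TUBE_AP_OFFSET_MM, SPHERE_SEPARATION_MM / 2.0)


def build_body_phantom(
    sphere_concentration_kbq_ml: float = 15.0,
    tube_concentration_kbq_ml: float = 15.0,
) -> Phantom:
    """Body phantom with two 28-mm hot spheres on the scanner axis direction
    and a transverse tube-shaped chamber whose anteroposterior projection
    overlaps sphere 1 but not sphere 2.

    Sphere 1 (overlapped) sits superior, sphere 2 (reference) inferior,
    80 mm apart; the tube lies 60 mm anterior of sphere 1 with its long
    axis left-right.  Spheres carry the 350-HU contrast attenuation class.
    """
    body = Primitive(
        "cylinder", (0.0, 0.0, 0.0),
        (BODY_OUTLINE_LR_MM, BODY_OUTLINE_AP_MM, BODY_OUTLINE_HEIGHT_MM),
        activity_concentration=0.0, attenuation_class="water", axis="z",
    )
    sphere1 = Primitive(
        "sphere", SPHERE1_CENTER, (SPHERE_DIAMETER_MM,),
        activity_concentration=sphere_concentration_kbq_ml,
        attenuation_class="contrast_350HU",
    )
    sphere2 = Primitive(
        "sphere", SPHERE2_CENTER, (SPHERE_DIAMETER_MM,),
        activity_concentration=sphere_concentration_kbq_ml,
        attenuation_class="contrast_350HU",
    )
    tube = Primitive(
        "cylinder", TUBE_CENTER, (TUBE_DIAMETER_MM, TUBE_LENGTH_MM),
        activity_concentration=tube_concentration_kbq_ml,
        attenuation_class="water", axis="x",
    )
    return Phantom(body_outline=body, primitives=(sphere1, sphere2, tube))


# ---------------------------------------------------------------------------
# Synthetic lesion cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionCohortSpec:
    """Paired-lesion cohort: a shared latent log lesion-to-background
    contrast per lesion plus independent per-tracer multiplicative noise.

    Stand-in for a clinical bone-metastasis cohort imaged with two tracers.
    """

    n_lesions: int = 36
    latent_mean: float = 2.2   # mean log contrast (median contrast ~9)
    latent_sd: float = 0.5
    tracer_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.latent_sd < 0 or self.tracer_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def generate_lesion_cohort(spec: LesionCohortSpec) -> np.ndarray:
    """Return an (n_lesions, 2) array of true lesion-to-background uptake
    contrasts for tracers A and B.

    ``log(uptake) = latent + noise_tracer`` with ``latent ~ N(mean, sd^2)``
    shared within a pair and independent N(0, noise_sd^2) per tracer, so the
    log-scale pair correlation is ``sd^2 / (sd^2 + noise_sd^2)``.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    latent = rng.normal(spec.latent_mean, spec.latent_sd, size=spec.n_lesions)
    noise = rng.normal(0.0, spec.tracer_noise_sd, size=(spec.n_lesions, 2))
    return np.exp(latent[:, None] + noise)
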