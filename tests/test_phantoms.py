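"""Phantom geometry, voxelization and lesion-cohort generation."""

import numpy as np
import pytest

from ra223spect.phantoms import (
    GeometryError,
    LesionCohortSpec,
    Phantom,
    Primitive,
    SPHERE1_CENTER,
    SPHERE2_CENTER,
    TUBE_CENTER,
    VoxelGrid,
    build_body_phantom,
    build_cylindrical_phantom,
    generate_lesion_cohort,
    voxelize,
)


class TestPrimitives:
    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            Primitive("sphere", (0, 0, 0), (-5.0,))
        with pytest.raises(ValueError):
            Primitive("sphere", (0, 0, 0), (5.0,), activity_concentration=-1)
        with pytest.raises(ValueError):
            Primitive("blob", (0, 0, 0), (5.0,))

    def test_analytic_volumes(self):
        sphere = Primitive("sphere", (0, 0, 0), (28.0,))
        assert sphere.volume_ml() == pytest.approx(4 / 3 * np.pi * 1.4**3)
        cyl = Primitive("cylinder", (0, 0, 0), (45.0, 200.0))
        assert cyl.volume_ml() == pytest.approx(np.pi * 2.25**2 * 20.0)

    def test_cylinder_axis_orientation(self):
        tube = Primitive("cylinder", (0, 0, 0), (30.0, 150.0), axis="x")
        assert tube.contains(np.array([[70.0, 0.0, 0.0]]))[0]
        assert not tube.contains(np.array([[80.0, 0.0, 0.0]]))[0]
        assert not tube.contains(np.array([[0.0, 16.0, 0.0]]))[0]


class TestCylindricalPhantom:
    def test_rod_volume_and_activity(self):
        ph = build_cylindrical_phantom()
        rod = ph.primitives[0]
        assert rod.volume_ml() == pytest.approx(318.086, abs=0.1)
        assert rod.total_activity_kbq() == pytest.approx(636.17, abs=0.2)

    def test_rod_on_phantom_axis(self):
        ph = build_cylindrical_phantom()
        rod, body = ph.primitives[0], ph.body_outline
        assert np.allclose(rod.center[:2], body.center[:2])  # collinear axes

    def test_background_is_cold_water(self):
        ph = build_cylindrical_phantom()
        assert ph.body_outline.activity_concentration == 0.0
        assert ph.body_outline.attenuation_class == "water"


class TestBodyPhantom:
    def test_sphere_volume_is_11_5_cm3(self):
        ph = build_body_phantom()
        for sphere in ph.primitives[:2]:
            assert sphere.volume_ml() == pytest.approx(11.49, abs=0.01)

    @staticmethod
    def _ap_ray_hits(primitive, x, z):
        """Does the anteroposterior (y-direction) ray at (x, z) intersect?"""
        ys = np.linspace(-100, 100, 2001)
        pts = np.column_stack([np.full_like(ys, x), ys, np.full_like(ys, z)])
        return bool(primitive.contains(pts).any())

    def test_tube_overlaps_sphere1_only_in_ap_projection(self):
        ph = build_body_phantom()
        tube = ph.primitives[2]
        assert self._ap_ray_hits(tube, SPHERE1_CENTER[0], SPHERE1_CENTER[2])
        assert not self._ap_ray_hits(tube, SPHERE2_CENTER[0], SPHERE2_CENTER[2])

    def test_spheres_share_longitudinal_axis(self):
        assert SPHERE1_CENTER[:2] == SPHERE2_CENTER[:2]
        assert SPHERE1_CENTER[2] != SPHERE2_CENTER[2]

    def test_tube_anterior_of_sphere1(self):
        assert TUBE_CENTER[1] > SPHERE1_CENTER[1]
        assert TUBE_CENTER[2] == SPHERE1_CENTER[2]


def _brute_force_sphere_voxels(diameter, grid):
    """Independent voxel-centre counting oracle."""
    n = 0
    r2 = (diameter / 2.0) ** 2
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                c = grid.origin + (np.array([i, j, k]) + 0.5) * grid.voxel_size
                if (c**2).sum() <= r2:
                    n += 1
    return n


class TestVoxelize:
    def _sphere_phantom(self, diameter=28.0, conc=1.0):
        body = Primitive("box", (0, 0, 0), (60.0, 60.0, 60.0), 0.0, "water")
        sphere = Primitive("sphere", (0, 0, 0), (diameter,), conc, "water")
        return Phantom(body_outline=body, primitives=(sphere,))

    def test_sphere_volume_on_2mm_grid_within_2pct(self):
        ph = self._sphere_phantom()
        grid = VoxelGrid.centered((31, 31, 31), 2.0)  # odd: centre-aligned
        act = voxelize(ph, grid, "activity")
        measured = float((act.values > 0).sum()) * act.voxel_volume_ml
        assert measured == pytest.approx(11.49, rel=0.02)

    def test_matches_voxel_center_oracle(self):
        ph = self._sphere_phantom()
        grid = VoxelGrid.centered((16, 16, 16), 4.0)
        act = voxelize(ph, grid, "activity")
        assert int((act.values > 0).sum()) == _brute_force_sphere_voxels(28.0, grid)

    def test_empty_phantom_all_zero(self):
        body = Primitive("box", (0, 0, 0), (60.0, 60.0, 60.0), 0.0, "water")
        grid = VoxelGrid.centered((10, 10, 10), 8.0)
        act = voxelize(Phantom(body_outline=body), grid, "activity")
        assert not act.values.any()

    def test_uniform_water_attenuation_fill(self):
        body = Primitive("cylinder", (0, 0, 0), (70.0, 70.0), 0.0, "water")
        grid = VoxelGrid.centered((20, 20, 20), 4.0)
        mu = voxelize(
            Phantom(body_outline=body), grid, "attenuation",
            attenuation_coefficients={"water": 0.18},
        )
        inside = mu.values[mu.values > 0]
        assert inside.size > 0
        assert np.allclose(inside, 0.18)

    def test_overlap_later_primitive_wins(self):
        body = Primitive("box", (0, 0, 0), (80.0, 80.0, 80.0), 0.0, "water")
        a = Primitive("sphere", (0, 0, 0), (40.0,), 1.0, "water")
        b = Primitive("sphere", (5.0, 0, 0), (40.0,), 7.0, "water")
        grid = VoxelGrid.centered((20, 20, 20), 4.0)
        act = voxelize(Phantom(body, (a, b)), grid, "activity")
        # centre voxel is inside both spheres: the later sphere's value wins
        assert act.values[10, 10, 10] == 7.0

    def test_grid_must_cover_phantom(self):
        ph = self._sphere_phantom()
        grid = VoxelGrid.centered((5, 5, 5), 4.0)  # 20 mm cube < body box
        with pytest.raises(GeometryError):
            voxelize(ph, grid, "activity")

    def test_volume_error_shrinks_with_voxel_size(self):
        """Voxelized total activity converges to the analytic value: the
        relative error at least halves from 4 mm to 2 mm to 1 mm grids."""
        ph = self._sphere_phantom(conc=3.0)
        truth = ph.primitives[0].total_activity_kbq()
        errors = []
        for size, n in ((4.0, 16), (2.0, 32), (1.0, 64)):
            grid = VoxelGrid.centered((n, n, n), size)
            act = voxelize(ph, grid, "activity")
            errors.append(abs(act.total_activity_kbq() - truth) / truth)
        assert errors[1] <= errors[0] / 2.0 + 1e-12
        assert errors[2] <= errors[1] / 2.0 + 1e-12

    def test_supersampling_improves_volume_estimate(self):
        ph = self._sphere_phantom(conc=1.0)
        truth = ph.primitives[0].total_activity_kbq()
        grid = VoxelGrid.centered((10, 10, 10), 6.0)
        err1 = abs(voxelize(ph, grid, "activity").total_activity_kbq() - truth)
        err4 = abs(
            voxelize(ph, grid, "activity", supersample=4).total_activity_kbq()
            - truth
        )
        assert err4 < err1


class TestLesionCohort:
    def test_reproducible_under_fixed_seed(self):
        spec = LesionCohortSpec(n_lesions=20, seed=7)
        a = generate_lesion_cohort(spec)
        b = generate_lesion_cohort(spec)
        assert np.array_equal(a, b)

    def test_zero_noise_gives_perfect_log_correlation(self):
        spec = LesionCohortSpec(n_lesions=30, tracer_noise_sd=0.0, seed=3)
        pairs = np.log(generate_lesion_cohort(spec))
        assert np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1] == pytest.approx(1.0)

    def test_mean_correlation_matches_monte_carlo_oracle(self):
        """Empirical mean Pearson r of the log pairs over many cohorts must
        match an independent direct simulation of the shared-latent model
        (latent sd 0.5, per-tracer noise sd 0.4)."""
        spec = LesionCohortSpec(
            n_lesions=36, latent_sd=0.5, tracer_noise_sd=0.4, seed=0
        )
        rs = []
        for seed in range(300):
            pairs = np.log(
                generate_lesion_cohort(
                    LesionCohortSpec(36, spec.latent_mean, 0.5, 0.4, seed)
                )
            )
            rs.append(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])
        # independent oracle: simulate the latent + noise model directly
        oracle_rng = np.random.default_rng(999)
        oracle_rs = []
        for _ in range(300):
            lat = oracle_rng.normal(0, 0.5, 36)
            x = lat + oracle_rng.normal(0, 0.4, 36)
            y = lat + oracle_rng.normal(0, 0.4, 36)
            oracle_rs.append(np.corrcoef(x, y)[0, 1])
        assert np.mean(rs) == pytest.approx(np.mean(oracle_rs), abs=0.03)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LesionCohortSpec(n_lesions=0)
        with pytest.raises(ValueError):
            LesionCohortSpec(tracer_noise_sd=-0.1)
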