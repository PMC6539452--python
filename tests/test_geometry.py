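"""Pinhole response, scatter angles, ray tracing, field of view."""

import numpy as np
import pytest

from xfct.geometry import (
    SystemGeometry,
    VoxelGrid,
    fov_diameter,
    pinhole_response,
    prf_matrix,
    rotate_map_to_lab,
    sampled_path_integrals,
    scatter_angle,
    trace_line_integral,
    trace_ray,
)


class TestFov:
    def test_default_geometry_exceeds_50mm(self, geom):
        assert fov_diameter(geom) > 50.0

    def test_unit_magnification(self):
        g = SystemGeometry(pinhole_to_center=60.0, pinhole_to_detector=60.0)
        assert fov_diameter(g) == pytest.approx(g.detector_length)

    def test_halving_detector_distance_doubles_fov(self, geom):
        g2 = SystemGeometry(pinhole_to_detector=geom.pinhole_to_detector / 2)
        assert fov_diameter(g2) == pytest.approx(2 * fov_diameter(geom))


class TestScatterAngle:
    def test_center_voxel_orthogonal_detector(self, geom):
        assert scatter_angle((0.0, 0.0), (1.0, 0.0), geom) == pytest.approx(np.pi / 2)

    def test_hand_trigonometry_45_degrees(self, geom):
        # voxel 75 mm towards the source, pinhole 75 mm off-axis at 90 deg
        assert scatter_angle((-75.0, 0.0), (1.0, 0.0), geom) == pytest.approx(np.pi / 4)

    def test_forward_scatter_zero(self, geom):
        v = np.array([0.0, -10.0])
        beam = geom.pinhole_position - v
        assert scatter_angle(v, beam, geom) == pytest.approx(0.0, abs=1e-7)

    def test_invariant_under_rigid_rotation(self, geom):
        delta = 25.0
        rotated = SystemGeometry(detector_side_angle=geom.detector_side_angle + delta)
        a = np.deg2rad(delta)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        for v in ((5.0, -3.0), (-12.0, 8.0)):
            base = scatter_angle(v, (1.0, 0.0), geom)
            moved = scatter_angle(rot @ np.asarray(v), rot @ np.array([1.0, 0.0]), rotated)
            assert moved == pytest.approx(base, rel=1e-12)


class TestPinholeResponse:
    def test_geometric_miss_is_zero(self, geom):
        v = (20.0, 0.0)
        row = prf_matrix(np.array([v]), geom).toarray().ravel()
        hit = int(np.argmax(row))
        assert pinhole_response(v, hit, geom) > 0
        # three pixels away from the (sub-pixel-wide) image: geometric miss
        assert pinhole_response(v, hit + 3, geom) == 0.0
        assert pinhole_response(v, hit - 3, geom) == 0.0

    def test_mirror_symmetry(self, geom):
        v = (7.3, -4.0)
        mirrored = (-7.3, -4.0)
        for pix in range(geom.detector_pixels):
            lhs = pinhole_response(v, pix, geom)
            rhs = pinhole_response(mirrored, geom.detector_pixels - 1 - pix, geom)
            assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-18)

    def test_row_sum_equals_total_aperture_solid_angle(self, geom):
        """No photons are lost between pixels: sum over pixels = A cos(chi)/(4 pi d^2)."""
        pts = np.array([[0.0, 0.0], [5.0, -10.0], [-8.0, 12.0]])
        m = prf_matrix(pts, geom)
        p = geom.pinhole_position
        for i, v in enumerate(pts):
            d = np.linalg.norm(p - v)
            cos_chi = (p - v) @ geom.axis / d
            expected = geom.aperture_width * geom.aperture_height * cos_chi / (4 * np.pi * d**2)
            assert m[i].sum() == pytest.approx(expected, rel=1e-12)

    def test_matches_scalar_api(self, geom):
        pts = np.array([[3.7, -5.0]])
        row = prf_matrix(pts, geom).toarray().ravel()
        for pix in np.nonzero(row)[0]:
            assert row[pix] == pytest.approx(pinhole_response(pts[0], int(pix), geom))

    def test_monte_carlo_solid_angle_oracle(self, geom):
        """Isotropic 3D ray sampling through the rectangular aperture onto a pixel."""
        rng = np.random.default_rng(42)
        voxel = np.array([3.7, -5.0])
        p = geom.pinhole_position
        d3 = np.append(p - voxel, 0.0)
        dist = np.linalg.norm(d3)
        dhat = d3 / dist
        half = 1.3 * np.hypot(geom.aperture_width / 2, geom.aperture_height / 2) / dist
        n = 2_000_000
        cos_min = np.cos(half)
        u = rng.uniform(cos_min, 1.0, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        sin_t = np.sqrt(1 - u**2)
        up = np.array([0.0, 0.0, 1.0])
        side = np.cross(dhat, up)
        dirs = (
            u[:, None] * dhat
            + (sin_t * np.cos(phi))[:, None] * side
            + (sin_t * np.sin(phi))[:, None] * up
        )
        v3 = np.append(voxel, 0.0)
        p3 = np.append(p, 0.0)
        n3 = np.append(geom.axis, 0.0)
        t_ap = ((p3 - v3) @ n3) / (dirs @ n3)
        hit = v3 + t_ap[:, None] * dirs
        lat = (hit - p3) @ np.append(geom.lateral, 0.0)
        through = (
            (t_ap > 0)
            & (np.abs(lat) <= geom.aperture_width / 2)
            & (np.abs(hit[:, 2]) <= geom.aperture_height / 2)
        )
        det_dist = geom.pinhole_to_center + geom.pinhole_to_detector
        t_det = (det_dist - v3 @ n3) / (dirs @ n3)
        hit_det = v3 + t_det[:, None] * dirs
        lat_det = (hit_det - det_dist * n3) @ np.append(geom.lateral, 0.0)
        centers = geom.pixel_lateral_centers()
        cap_frac = (1 - cos_min) / 2.0
        row = prf_matrix(voxel[None, :], geom).toarray().ravel()
        pix = int(np.argmax(row))
        in_pix = through & (np.abs(lat_det - centers[pix]) <= geom.pixel_width / 2)
        mc = cap_frac * in_pix.mean()
        assert pinhole_response(voxel, pix, geom) == pytest.approx(mc, rel=0.01)


class TestRayTracing:
    def test_uniform_slab(self):
        grid = VoxelGrid(32, 32, 1.0)
        mu = np.full(grid.shape, 0.2)
        # 30 mm = 3 cm chord fully inside the grid
        assert trace_line_integral((-15.0, 2.2), (15.0, 2.2), mu, grid) == pytest.approx(0.6)

    def test_vacuum_and_degenerate(self):
        grid = VoxelGrid(16, 16, 1.0)
        zeros = np.zeros(grid.shape)
        assert trace_line_integral((-5, -5), (5, 5), zeros, grid) == 0.0
        mu = np.ones(grid.shape)
        assert trace_line_integral((1.0, 1.0), (1.0, 1.0), mu, grid) == 0.0

    def test_chord_length_conservation(self):
        grid = VoxelGrid(24, 24, 0.75)
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform(-8, 8, 2)
            b = rng.uniform(-8, 8, 2)
            path = trace_ray(a, b, grid)
            assert path.lengths.sum() == pytest.approx(np.linalg.norm(b - a), rel=1e-9)

    def test_dense_sampling_oracle(self):
        """Siddon traversal against 1e4-point midpoint sampling of the voxel field."""
        rng = np.random.default_rng(11)
        grid = VoxelGrid(32, 32, 1.0)
        mu = rng.uniform(0.05, 0.5, grid.shape)
        for _ in range(50):
            a = rng.uniform(-14, 14, 2)
            b = rng.uniform(-14, 14, 2)
            got = trace_line_integral(a, b, mu, grid)
            n = 10_000
            frac = (np.arange(n) + 0.5) / n
            pts = a + frac[:, None] * (b - a)
            ix = np.clip(((pts[:, 0] - grid.origin[0]) / grid.pixel_size).astype(int), 0, 31)
            iy = np.clip(((pts[:, 1] - grid.origin[1]) / grid.pixel_size).astype(int), 0, 31)
            inside = (
                (pts[:, 0] >= grid.origin[0]) & (pts[:, 0] < -grid.origin[0])
                & (pts[:, 1] >= grid.origin[1]) & (pts[:, 1] < -grid.origin[1])
            )
            ref = np.sum(mu[iy, ix] * inside) / n * np.linalg.norm(b - a) / 10.0
            if ref > 1e-4:
                assert got == pytest.approx(ref, rel=1.5e-3)

    def test_additive_under_segment_split(self):
        grid = VoxelGrid(32, 32, 1.0)
        rng = np.random.default_rng(5)
        mu = rng.uniform(0.1, 0.4, grid.shape)
        a, c = np.array([-13.0, -7.0]), np.array([12.0, 9.0])
        b = a + 0.37 * (c - a)
        whole = trace_line_integral(a, c, mu, grid)
        split = trace_line_integral(a, b, mu, grid) + trace_line_integral(b, c, mu, grid)
        assert split == pytest.approx(whole, rel=1e-9)

    def test_sampled_path_integrals_on_smooth_map(self, geom):
        """Bilinear-sampled exit-leg integrals track the exact traversal on smooth maps."""
        grid = VoxelGrid(64, 64, 0.5)
        c = grid.voxel_centers()
        r2 = (c[:, 0] ** 2 + c[:, 1] ** 2).reshape(grid.shape)
        mu = 0.3 * np.exp(-r2 / (2 * 8.0**2))
        rng = np.random.default_rng(9)
        pts = rng.uniform(-12, 12, (30, 2))
        got = sampled_path_integrals(mu, grid, pts, geom.pinhole_position, n_samples=400)
        ref = np.array([
            trace_line_integral(p, geom.pinhole_position, mu, grid) for p in pts
        ])
        assert np.allclose(got, ref, rtol=0.02, atol=1.5e-3)


class TestRotation:
    def test_zero_angle_identity(self):
        grid = VoxelGrid(16, 16, 1.0)
        m = np.arange(256, dtype=float).reshape(16, 16)
        assert np.array_equal(rotate_map_to_lab(m, grid, 0.0), m)

    def test_centered_disc_invariant(self):
        grid = VoxelGrid(64, 64, 0.5)
        c = grid.voxel_centers()
        disc = ((c[:, 0] ** 2 + c[:, 1] ** 2) < 100.0).reshape(grid.shape).astype(float)
        rot = rotate_map_to_lab(disc, grid, 73.0)
        assert np.abs(rot - disc).sum() / disc.sum() < 0.05
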