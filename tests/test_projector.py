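"""Cone-beam projector: line-integral accuracy and adjointness."""

import numpy as np
import pytest

import cbctraj as c
from cbctraj.cli import fit_detector

RAO = c.Family.RAO_LAO


def supersampled_ellipsoid(n: int, spacing: float, semi_axes, ss: int = 4) -> c.Volume:
    """Unit-density ellipsoid voxelized with ``ss``× antialiasing."""
    semi = np.asarray(semi_axes, dtype=float)
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing
    acc = np.zeros((n, n, n))
    for ox in offs:
        for oy in offs:
            for oz in offs:
                x = (coords + ox * spacing)[:, None, None]
                y = (coords + oy * spacing)[None, :, None]
                z = (coords + oz * spacing)[None, None, :]
                acc += (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0
    return c.Volume.centered(acc / ss**3, spacing)


def analytic_chords(pose: c.Pose, geom: c.GeometryParams, semi_axes) -> np.ndarray:
    """Closed-form ray-ellipsoid chord length for every detector pixel."""
    semi = np.asarray(semi_axes, dtype=float)
    s = pose.source_position
    nu, nv = geom.detector_size
    pitch = geom.detector_pixel_pitch_mm
    us = (np.arange(nu) - (nu - 1) / 2.0) * pitch
    vs = (np.arange(nv) - (nv - 1) / 2.0) * pitch
    pix = (
        pose.detector_center[None, None, :]
        + us[:, None, None] * pose.detector_u_axis
        + vs[None, :, None] * pose.detector_v_axis
    )
    d = pix - s
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    a = np.sum((d / semi) ** 2, axis=-1)
    b = 2.0 * np.sum(d * s / semi**2, axis=-1)
    cc = np.sum((s / semi) ** 2) - 1.0
    disc = b * b - 4.0 * a * cc
    return np.where(disc > 0, np.sqrt(np.maximum(disc, 0.0)) / a, 0.0)


@pytest.fixture(scope="module")
def dot_geom() -> c.GeometryParams:
    return fit_detector(64, 32.0)


def pose_at(primary, oblique, geom, family=RAO):
    return c.pose_from_angles(c.AnglePair(family, primary, oblique), geom)


class TestForwardProject:
    def test_zero_volume_projects_to_zero(self, small_geom):
        vol = c.Volume.centered(np.zeros((16, 16, 16)), 2.0)
        stack = c.forward_project(vol, [pose_at(25, -10, small_geom)], small_geom)
        assert np.all(stack.images[0] == 0.0)

    def test_cube_central_ray_equals_edge_length(self):
        vox = np.zeros((64, 64, 64))
        vox[16:48, 16:48, 16:48] = 1.0
        vol = c.Volume.centered(vox, 1.0)
        geom = c.GeometryParams(detector_size=(65, 65), detector_pixel_pitch_mm=2.0)
        img = c.forward_project(vol, [pose_at(0, 0, geom)], geom).images[0]
        assert img[32, 32] == pytest.approx(32.0, rel=0.01)

    def test_ellipsoid_matches_closed_form_chords(self):
        """Interior rays reproduce the analytic ray-ellipsoid chord length."""
        semi = (24.0, 18.0, 28.0)
        vol = supersampled_ellipsoid(64, 1.0, semi)
        geom = fit_detector(128, 64.0)
        for primary, oblique in [(0, 0), (33, 11)]:
            pose = pose_at(primary, oblique, geom)
            img = c.forward_project(vol, [pose], geom).images[0]
            chord = analytic_chords(pose, geom, semi)
            mask = chord > 0.5 * chord.max()
            rel = np.abs(img - chord)[mask] / chord[mask]
            assert rel.max() < 0.02

    def test_linearity(self, small_geom, rng):
        x = rng.random((16, 16, 16))
        y = rng.random((16, 16, 16))
        pose = [pose_at(40, 5, small_geom)]
        px = c.forward_project(c.Volume.centered(x, 2.0), pose, small_geom).images[0]
        py = c.forward_project(c.Volume.centered(y, 2.0), pose, small_geom).images[0]
        pxy = c.forward_project(
            c.Volume.centered(2.5 * x - 0.7 * y, 2.0), pose, small_geom
        ).images[0]
        np.testing.assert_allclose(pxy, 2.5 * px - 0.7 * py, rtol=1e-6, atol=1e-9)

    def test_rotation_consistency_for_centered_smooth_sphere(self):
        """A centered radially smooth ball projects identically from any angle."""
        n = 96
        coords = (np.arange(n) - (n - 1) / 2.0) * 1.0
        r2 = (
            coords[:, None, None] ** 2
            + coords[None, :, None] ** 2
            + coords[None, None, :] ** 2
        )
        vol = c.Volume.centered(np.exp(-r2 / (2 * 12.0**2)), 1.0)
        geom = fit_detector(32, 96.0)
        images = [
            c.forward_project(vol, [pose_at(p, o, geom, fam)], geom).images[0]
            for p, o, fam in [(0, 0, RAO), (90, 0, RAO), (45, 30, RAO),
                              (30, -50, c.Family.CRA_CAU)]
        ]
        ref = images[0]
        for img in images[1:]:
            assert np.max(np.abs(img - ref)) / ref.max() < 1e-3

    def test_source_inside_volume_rejected(self, small_geom):
        vol = c.Volume.centered(np.ones((8, 8, 8)), 500.0)
        with pytest.raises(ValueError, match="degenerate"):
            c.forward_project(vol, [pose_at(0, 0, small_geom)], small_geom)

    def test_empty_pose_list_rejected(self, small_geom):
        vol = c.Volume.centered(np.ones((8, 8, 8)), 1.0)
        with pytest.raises(ValueError):
            c.forward_project(vol, [], small_geom)


class TestBackproject:
    def test_zero_projections_give_zero_volume(self, dot_geom):
        pose = pose_at(10, 3, dot_geom)
        stack = c.ProjectionStack(
            [np.zeros(dot_geom.detector_size)], [pose], dot_geom.detector_pixel_pitch_mm
        )
        grid = c.GridSpec((32, 32, 32), np.ones(3), -np.full(3, 15.5))
        assert np.all(c.backproject(stack, grid, dot_geom).voxels == 0.0)

    def test_single_pixel_backprojects_to_nonnegative_ray(self, dot_geom):
        pose = pose_at(0, 0, dot_geom)
        img = np.zeros(dot_geom.detector_size)
        img[32, 32] = 1.0
        stack = c.ProjectionStack([img], [pose], dot_geom.detector_pixel_pitch_mm)
        grid = c.GridSpec((32, 32, 32), np.ones(3), -np.full(3, 15.5))
        vol = c.backproject(stack, grid, dot_geom).voxels
        assert vol.min() >= 0.0 and vol.max() > 0.0
        # support concentrated near the central axis
        assert vol[:, :, 0].sum() == pytest.approx(0.0, abs=1e-12)

    def test_adjoint_dot_test(self, dot_geom, rng):
        """<Ax, y> == <x, A'y> for random volumes/projections (20 draws)."""
        grid = c.GridSpec((32, 32, 32), np.ones(3), -np.full(3, 15.5))
        poses = [pose_at(float(rng.uniform(-120, 120)), float(rng.uniform(-40, 40)),
                         dot_geom) for _ in range(20)]
        for pose in poses:
            x = rng.random(grid.shape)
            Ax = c.forward_project(c.Volume(x, grid.spacing, grid.origin), [pose],
                                   dot_geom).images[0]
            y = rng.random(Ax.shape)
            stack = c.ProjectionStack([y], [pose], dot_geom.detector_pixel_pitch_mm)
            Aty = c.backproject(stack, grid, dot_geom).voxels
            lhs = float(np.sum(Ax * y))
            rhs = float(np.sum(x * Aty))
            assert lhs == pytest.approx(rhs, rel=0.01)

    def test_shape_mismatch_rejected(self, dot_geom):
        pose = pose_at(0, 0, dot_geom)
        stack = c.ProjectionStack([np.zeros((8, 8))], [pose], 1.0)
        grid = c.GridSpec((16, 16, 16), np.ones(3), -np.full(3, 7.5))
        with pytest.raises(ValueError):
            c.backproject(stack, grid, dot_geom)


def test_volume_validation():
    with pytest.raises(ValueError):
        c.Volume(np.ones((4, 4, 4)), np.array([1.0, -1.0, 1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        c.Volume(np.full((4, 4, 4), np.nan), np.ones(3), np.zeros(3))


def test_hu_to_attenuation_affine_and_clipped():
    vol = c.Volume.centered(np.array([[[-1000.0, 0.0, 1000.0, -2000.0]]]), 1.0)
    mu = c.hu_to_attenuation(vol).voxels.ravel()
    assert mu[0] == pytest.approx(0.0)
    assert mu[1] == pytest.approx(0.02)
    assert mu[2] == pytest.approx(0.04)
    assert mu[3] == 0.0  # clipped
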