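"""Matched cone-beam projector / backprojector pair.

The forward model is a line-integral sampler: for every detector pixel, the
ray from the source through the pixel center is clipped against the volume
bounding box and integrated by the midpoint rule with trilinear
interpolation at a sub-voxel step (default half the smallest voxel side).
The backprojector scatters with exactly the same sample positions and
interpolation weights, so the pair is adjoint to floating-point precision —
a property the algebraic reconstruction in :mod:`cbctraj.recon` relies on.

Volumes carry their voxel grid, isotropic-or-not spacing and world origin;
world coordinates are millimetres with the isocenter at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import GeometryParams, Pose

# Attenuation scale used when converting Hounsfield units to linear
# attenuation: mu = MU_WATER_PER_MM * (1 + HU/1000), clipped at zero.
MU_WATER_PER_MM = 0.02


@dataclass
class Volume:
    """A scalar voxel grid in world (mm) coordinates.

    ``voxels`` is indexed ``[ix, iy, iz]``; the world position of voxel
    ``(i, j, k)`` center is ``origin + (i, j, k) * spacing``.
    """

    voxels: np.ndarray
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, center of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @classmethod
    def centered(cls, voxels: np.ndarray, spacing: float | Sequence[float]) -> "Volume":
        """Volume whose grid is centered on the isocenter."""
        voxels = np.asarray(voxels, dtype=np.float64)
        sp = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
        origin = -(np.array(voxels.shape) - 1) / 2.0 * sp
        return cls(voxels, sp, origin)

    def like(self, voxels: np.ndarray) -> "Volume":
        return Volume(voxels, self.spacing.copy(), self.origin.copy())

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (voxel faces, half a voxel beyond the centers)."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.voxels.shape) - 0.5) * self.spacing
        return lo, hi


@dataclass
class GridSpec:
    """Shape/spacing/origin of a reconstruction grid (no voxel data)."""

    shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray

    @classmethod
    def of(cls, volume: Volume) -> "GridSpec":
        return cls(volume.voxels.shape, volume.spacing.copy(), volume.origin.copy())

    def zeros(self) -> Volume:
        return Volume(np.zeros(self.shape), self.spacing, self.origin)


@dataclass
class ProjectionStack:
    """2D projections aligned 1:1 with their acquisition poses."""

    images: list[np.ndarray]  # each (n_u, n_v)
    poses: list[Pose]
    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        if len(self.images) != len(self.poses):
            raise ValueError("images and poses must align 1:1")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("all projection images must share one shape")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx: Sequence[int]) -> "ProjectionStack":
        return ProjectionStack(
            [self.images[i] for i in idx], [self.poses[i] for i in idx], self.pixel_pitch_mm
        )

    @staticmethod
    def concatenate(stacks: Sequence["ProjectionStack"]) -> "ProjectionStack":
        stacks = [s for s in stacks if len(s)]
        if not stacks:
            raise ValueError("nothing to concatenate")
        pitch = stacks[0].pixel_pitch_mm
        images, poses = [], []
        for s in stacks:
            if s.pixel_pitch_mm != pitch:
                raise ValueError("pixel pitch mismatch")
            images.extend(s.images)
            poses.extend(s.poses)
        return ProjectionStack(images, poses, pitch)


def hu_to_attenuation(volume: Volume, mu_water_per_mm: float = MU_WATER_PER_MM) -> Volume:
    """Affine HU → linear attenuation (1/mm) map, clipped at zero."""
    mu = mu_water_per_mm * (1.0 + volume.voxels / 1000.0)
    return volume.like(np.clip(mu, 0.0, None))


def _detector_pixel_centers(pose: Pose, params: GeometryParams) -> np.ndarray:
    nu, nv = params.detector_size
    pitch = params.detector_pixel_pitch_mm
    du, dv = params.detector_offset_mm
    us = (np.arange(nu) - (nu - 1) / 2.0) * pitch + du
    vs = (np.arange(nv) - (nv - 1) / 2.0) * pitch + dv
    return (
        pose.detector_center[None, None, :]
        + us[:, None, None] * pose.detector_u_axis[None, None, :]
        + vs[None, :, None] * pose.detector_v_axis[None, None, :]
    )  # (nu, nv, 3)


def _ray_box_clip(
    source: np.ndarray, dirs: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit parameters of rays ``source + t*dirs`` against an AABB."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t_lo = (lo - source) * inv
        t_hi = (hi - source) * inv
    t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=-1)
    t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=-1)
    t_near = np.maximum(t_near, 0.0)
    return t_near, t_far


class _RaySampler:
    """Shared sample geometry for one pose (used by both A and Aᵀ)."""

    def __init__(self, volume_spec: GridSpec, pose: Pose, params: GeometryParams,
                 step_voxels: float) -> None:
        shape = np.array(volume_spec.shape)
        spacing = volume_spec.spacing
        origin = volume_spec.origin
        lo = origin - 0.5 * spacing
        hi = origin + (shape - 0.5) * spacing
        source = pose.source_position
        if np.all(source > lo) and np.all(source < hi):
            raise ValueError("degenerate pose: source lies inside the volume box")

        pix = _detector_pixel_centers(pose, params)  # (nu, nv, 3)
        d = pix - source[None, None, :]
        lengths = np.linalg.norm(d, axis=-1)
        d = d / lengths[..., None]
        t0, t1 = _ray_box_clip(source, d, lo, hi)
        hit = t1 > t0
        span = np.where(hit, t1 - t0, 0.0)
        step_mm = step_voxels * float(spacing.min())
        n_steps = max(int(np.ceil(span.max() / step_mm)), 1) if hit.any() else 1

        self.det_shape = tuple(pix.shape[:2])
        self.hit = hit
        self.n_steps = n_steps
        # per-ray step length (midpoint rule over each ray's own clipped span)
        self.dt = (span / n_steps)[hit]  # (R,)
        k = np.arange(n_steps) + 0.5
        ts = t0[hit][:, None] + self.dt[:, None] * k[None, :]  # (R, K)
        pts = source[None, None, :] + ts[..., None] * d[hit][:, None, :]
        # continuous voxel index coordinates (float32: sub-1e-5-voxel error,
        # and half the memory when samplers are cached across iterations)
        self.idx = ((pts - origin[None, None, :]) / spacing[None, None, :]).astype(
            np.float32
        )
        self.shape = tuple(int(s) for s in shape)

    @property
    def nbytes(self) -> int:
        return self.idx.nbytes + self.dt.nbytes

    def _corners(self):
        """Yield (flat_index, weight, valid_mask) for the 8 trilinear corners."""
        nx, ny, nz = self.shape
        i0 = np.floor(self.idx).astype(np.int64)  # (R, K, 3)
        frac = self.idx - i0
        for cx in (0, 1):
            wx = frac[..., 0] if cx else 1.0 - frac[..., 0]
            ix = i0[..., 0] + cx
            okx = (ix >= 0) & (ix < nx)
            for cy in (0, 1):
                wy = frac[..., 1] if cy else 1.0 - frac[..., 1]
                iy = i0[..., 1] + cy
                oky = (iy >= 0) & (iy < ny)
                for cz in (0, 1):
                    wz = frac[..., 2] if cz else 1.0 - frac[..., 2]
                    iz = i0[..., 2] + cz
                    ok = okx & oky & (iz >= 0) & (iz < nz)
                    w = wx * wy * wz
                    flat = (np.clip(ix, 0, nx - 1) * ny + np.clip(iy, 0, ny - 1)) * nz \
                        + np.clip(iz, 0, nz - 1)
                    yield flat, w, ok

    def project(self, voxels: np.ndarray) -> np.ndarray:
        flat_vol = voxels.ravel()
        acc = np.zeros(self.idx.shape[:2])  # (R, K)
        for flat, w, ok in self._corners():
            acc += np.where(ok, w * flat_vol[flat], 0.0)
        image = np.zeros(self.det_shape)
        image[self.hit] = acc.sum(axis=1) * self.dt
        return image

    def backproject(self, image: np.ndarray, out: np.ndarray) -> None:
        vals = image[self.hit] * self.dt  # (R,)
        contrib = np.broadcast_to(vals[:, None], self.idx.shape[:2])
        n_vox = out.size
        flat_out = out.ravel()
        for flat, w, ok in self._corners():
            weights = np.where(ok, w * contrib, 0.0)
            flat_out += np.bincount(flat.ravel(), weights=weights.ravel(), minlength=n_vox)


def forward_project(
    volume: Volume,
    poses: Sequence[Pose],
    params: GeometryParams,
    step_voxels: float = 0.5,
) -> ProjectionStack:
    """Cone-beam line integrals of ``volume`` for each pose.

    Pixels whose rays miss the volume are zero.  ``step_voxels`` sets the
    integration step as a fraction of the smallest voxel side.
    """
    if not poses:
        raise ValueError("need at least one pose")
    spec = GridSpec.of(volume)
    images = [
        _RaySampler(spec, pose, params, step_voxels).project(volume.voxels)
        for pose in poses
    ]
    return ProjectionStack(images, list(poses), params.detector_pixel_pitch_mm)


def backproject(
    stack: ProjectionStack,
    grid: GridSpec,
    params: GeometryParams,
    step_voxels: float = 0.5,
) -> Volume:
    """Adjoint of :func:`forward_project` on the same grid discretization."""
    nu, nv = params.detector_size
    if stack.images and stack.images[0].shape != (nu, nv):
        raise ValueError("projection shape does not match detector size")
    out = np.zeros(grid.shape)
    for image, pose in zip(stack.images, stack.poses):
        _RaySampler(grid, pose, params, step_voxels).backproject(image, out)
    return Volume(out, grid.spacing, grid.origin)
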