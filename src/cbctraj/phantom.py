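"""Synthetic digital phantom and study-scenario generator.

A thorax/neck-like analytic phantom stands in for a prior diagnostic CT: an
ellipsoidal soft-tissue body in air with high-contrast, vertebra-like
spherical inserts stacked along the patient's long axis (two "thoracic", one
"cervical").  Shapes are voxelized with 2× supersampling so boundaries carry
partial-volume fractions rather than hard steps, which keeps line integrals
and image metrics smooth.  Values are Hounsfield units; optional Gaussian
noise with a fixed seed emulates acquisition noise while keeping every run
bit-reproducible.

The module also provides the study conditions around the phantom: one VOI
per insert, and the two kinematic-constraint scenarios (one and two
forbidden angular regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arc_space import ForbiddenRegion
from .metrics import VOI
from .projector import Volume

HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_BONE = 1000.0


@dataclass(frozen=True)
class Insert:
    """A vertebra-like spherical insert, placed in world (mm) coordinates."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    hu: float = HU_BONE
    label: str = ""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity layout of the synthetic prior volume.

    The default 64³ grid at 1 mm spacing holds a body ellipsoid of
    soft tissue (40 HU) in air (−1000 HU) with three 1000 HU inserts: two
    mid-body ("thoracic") and one near the superior pole ("cervical").
    """

    grid_size: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    body_semi_axes_mm: tuple[float, float, float] = (28.0, 22.0, 30.0)
    body_hu: float = HU_SOFT_TISSUE
    background_hu: float = HU_AIR
    inserts: tuple[Insert, ...] = (
        Insert((0.0, 6.0, -14.0), 4.0, HU_BONE, "thoracic_lower"),
        Insert((0.0, 6.0, 2.0), 4.0, HU_BONE, "thoracic_upper"),
        Insert((0.0, 0.0, 20.0), 4.0, HU_BONE, "cervical"),
    )
    noise_sigma_hu: float = 0.0
    seed: int = 0
    supersampling: int = 2
    voi_half_width_voxels: int = 8

    def __post_init__(self) -> None:
        if min(self.grid_size) < 1 or self.spacing_mm <= 0:
            raise ValueError("invalid grid")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")
        for ins in self.inserts:
            rel = np.array(ins.center_mm) / np.array(self.body_semi_axes_mm)
            if np.sum(rel**2) > 1.0:
                raise ValueError(f"insert {ins.label!r} lies outside the body ellipsoid")


def _subvoxel_offsets(supersampling: int, spacing: float) -> np.ndarray:
    k = supersampling
    offs = (np.arange(k) + 0.5) / k - 0.5
    return offs * spacing


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Volume:
    """Voxelize the analytic phantom (HU values), centered on the isocenter."""
    shape = np.array(spec.grid_size)
    sp = spec.spacing_mm
    origin = -(shape - 1) / 2.0 * sp
    coords = [origin[a] + np.arange(shape[a]) * sp for a in range(3)]

    accum = np.zeros(tuple(shape))
    offs = _subvoxel_offsets(spec.supersampling, sp)
    semi = np.array(spec.body_semi_axes_mm)
    for ox in offs:
        x = (coords[0] + ox)[:, None, None]
        for oy in offs:
            y = (coords[1] + oy)[None, :, None]
            for oz in offs:
                z = (coords[2] + oz)[None, None, :]
                sub = np.full(tuple(shape), spec.background_hu)
                body = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0
                sub = np.where(body, spec.body_hu, sub)
                for ins in spec.inserts:
                    cx, cy, cz = ins.center_mm
                    inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= ins.radius_mm**2
                    sub = np.where(inside, ins.hu, sub)
                accum += sub
    voxels = accum / spec.supersampling**3

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sigma_hu, size=voxels.shape)
    return Volume(voxels, np.full(3, sp), origin)


def make_voi_targets(spec: PhantomSpec = PhantomSpec()) -> list[VOI]:
    """One VOI box per insert, centered on the insert's voxel index.

    Boxes are ``2·half_width`` voxels wide per axis (half-open ranges) and
    clipped to the volume; with the default layout they are pairwise
    disjoint.
    """
    shape = np.array(spec.grid_size)
    sp = spec.spacing_mm
    origin = -(shape - 1) / 2.0 * sp
    vois = []
    hw = spec.voi_half_width_voxels
    for ins in spec.inserts:
        idx = np.round((np.array(ins.center_mm) - origin) / sp).astype(int)
        lo = np.clip(idx - hw, 0, shape - 1)
        hi = np.clip(idx + hw, 1, shape)
        vois.append(VOI(tuple(int(v) for v in lo), tuple(int(v) for v in hi)))
    return vois


def make_forbidden_scenarios() -> dict[str, list[ForbiddenRegion]]:
    """The two kinematic-constraint scenarios of the study conditions.

    ``"one"`` simulates a single collision zone on the right/caudal side of
    the orientation sphere; ``"two"`` adds a second zone on the opposite
    side.  Both rectangles apply to both rotation families.
    """
    first = ForbiddenRegion(primary_range=(-120.0, -60.0), oblique_range=(-60.0, 0.0))
    second = ForbiddenRegion(primary_range=(30.0, 110.0), oblique_range=(0.0, 50.0))
    return {"one": [first], "two": [first, second]}
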