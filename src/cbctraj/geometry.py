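"""C-arm rotation geometry.

An isocentric C-arm has two rotation families:

* ``RAO_LAO`` — sweep by the primary angle θ₁ about the patient's
  longitudinal axis (Z), at a fixed cranial/caudal tilt ψ about X.
* ``CRA_CAU`` — sweep by the primary angle θ₂ about the patient's lateral
  axis (X), at a fixed right/left oblique tilt φ about Z.

The sign convention is (−) = right / caudal, (+) = left / cranial.  The
reference pose (all angles zero) puts the X-ray source on the −Y axis at the
source-to-isocenter distance, the detector opposite the source, the detector
u-axis along +X and the v-axis along +Z (the patient's long axis).

Angles are kept in degrees throughout the package; radians appear only
inside trigonometric calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class Family(str, Enum):
    """The two rotation families of an isocentric C-arm."""

    RAO_LAO = "RAO_LAO"
    CRA_CAU = "CRA_CAU"


@dataclass(frozen=True)
class GeometryParams:
    """Metric cone-beam geometry of the imaging system.

    Parameters
    ----------
    source_to_isocenter_mm
        Distance from the X-ray focal spot to the rotation isocenter (SAD).
    source_to_detector_mm
        Distance from the focal spot to the detector plane (SDD);
        must exceed the SAD.
    detector_size
        Flat-panel size in pixels, ``(n_u, n_v)``.
    detector_pixel_pitch_mm
        Side length of one detector pixel.
    detector_offset_mm
        In-plane shift ``(du, dv)`` of the panel center from the central ray.
    """

    source_to_isocenter_mm: float = 810.0
    source_to_detector_mm: float = 1195.0
    detector_size: tuple[int, int] = (128, 128)
    detector_pixel_pitch_mm: float = 1.0
    detector_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.source_to_isocenter_mm > 0 and self.source_to_detector_mm > 0):
            raise ValueError("distances must be positive")
        if self.source_to_detector_mm <= self.source_to_isocenter_mm:
            raise ValueError("source-to-detector distance must exceed source-to-isocenter")
        if min(self.detector_size) < 1 or self.detector_pixel_pitch_mm <= 0:
            raise ValueError("invalid detector specification")

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_isocenter_mm


@dataclass(frozen=True)
class AnglePair:
    """One C-arm orientation: a primary sweep angle at a fixed oblique tilt."""

    family: Family
    primary_deg: float
    oblique_deg: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.primary_deg) and np.isfinite(self.oblique_deg)):
            raise ValueError("angles must be finite")


@dataclass(frozen=True)
class Pose:
    """Source and detector placement for a single projection."""

    source_position: np.ndarray  # (3,) mm
    detector_center: np.ndarray  # (3,) mm
    detector_u_axis: np.ndarray  # unit vector
    detector_v_axis: np.ndarray  # unit vector
    angles: AnglePair | None = field(default=None, compare=False)


# Reference pose: source posterior (under-couch AP view).  Any consistent
# choice works since every quality comparison in the package is relative.
_REF_SOURCE = np.array([0.0, -1.0, 0.0])
_REF_U = np.array([1.0, 0.0, 0.0])
_REF_V = np.array([0.0, 0.0, 1.0])


def rotation_for(angles: AnglePair) -> Rotation:
    """World rotation for an angle pair: oblique tilt first, then the sweep.

    Tilt-then-sweep means a fixed oblique defines the plane in which the arc
    sweeps.  RAO/LAO sweeps about Z after an X tilt; CRA/CAU sweeps about X
    after a Z tilt.
    """
    if angles.family is Family.RAO_LAO:
        # extrinsic: first Rx(psi), then Rz(theta1)  ->  R = Rz(th1) @ Rx(psi)
        return Rotation.from_euler("xz", [angles.oblique_deg, angles.primary_deg], degrees=True)
    return Rotation.from_euler("zx", [angles.oblique_deg, angles.primary_deg], degrees=True)


def pose_from_angles(angles: AnglePair, params: GeometryParams) -> Pose:
    """Source/detector pose for one C-arm orientation.

    The reference pose is rotated rigidly, so the source-to-isocenter
    distance is preserved exactly and the central ray always passes through
    the isocenter perpendicular to the detector plane.
    """
    rot = rotation_for(angles)
    sad = params.source_to_isocenter_mm
    sdd = params.source_to_detector_mm
    source = rot.apply(_REF_SOURCE * sad)
    det_center = rot.apply(-_REF_SOURCE * (sdd - sad))
    u = rot.apply(_REF_U)
    v = rot.apply(_REF_V)
    return Pose(source, det_center, u, v, angles)


def sample_arc_angles(start: float, end: float, step: float = 1.0) -> np.ndarray:
    """Inclusive angular stations ``start, start+step, …, end``.

    The count is ``floor((end − start)/step) + 1``; a degenerate arc with
    ``start == end`` yields a single station.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not (np.isfinite(start) and np.isfinite(end)) or end < start:
        raise ValueError("need finite start <= end")
    n = int(np.floor((end - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def subsample_for_simulation(angles: Sequence[float], stride: int = 4) -> np.ndarray:
    """Every ``stride``-th station, starting at the first one.

    Used to thin 1°-sampled arcs for simulation-side reconstructions (an
    80-station arc at stride 4 keeps exactly 20 views); acquisitions always
    execute the full 1° sampling.
    """
    stride = int(stride)
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    return np.asarray(angles, dtype=float)[::stride]


def arc_poses(
    family: Family,
    oblique_deg: float,
    primary_angles: Sequence[float],
    params: GeometryParams,
) -> list[Pose]:
    """Poses for a sweep of primary angles at one fixed oblique tilt."""
    return [
        pose_from_angles(AnglePair(family, float(p), float(oblique_deg)), params)
        for p in primary_angles
    ]


def circular_angles(span_deg: float, n_views: int, center_deg: float = 0.0) -> np.ndarray:
    """Evenly spaced primary angles of a (partial) circular sweep."""
    if n_views < 1 or span_deg < 0:
        raise ValueError("need n_views >= 1 and span >= 0")
    if n_views == 1:
        return np.array([center_deg])
    return np.linspace(center_deg - span_deg / 2.0, center_deg + span_deg / 2.0, n_views)


def pose_records(poses: Sequence[Pose]) -> list[dict]:
    """JSON/CSV-friendly rows describing each pose."""
    rows = []
    for p in poses:
        a = p.angles
        rows.append(
            {
                "family": a.family.value if a else "",
                "primary_deg": a.primary_deg if a else float("nan"),
                "oblique_deg": a.oblique_deg if a else float("nan"),
                "source_xyz_mm": [float(x) for x in p.source_position],
                "detector_center_xyz_mm": [float(x) for x in p.detector_center],
                "u_axis": [float(x) for x in p.detector_u_axis],
                "v_axis": [float(x) for x in p.detector_v_axis],
            }
        )
    return rows
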