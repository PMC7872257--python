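"""Candidate arc space on the C-arm orientation sphere.

The search space is a set of short arcs (≤ 80° sweep each) in the two
rotation families, one arc per (family, oblique tilt, primary split).
Kinematic constraints — predicted collisions with the patient or with other
equipment — are modelled as *forbidden regions*: axis-aligned rectangles in
(primary, oblique) angle coordinates.  Arcs with more than a configurable
fraction of their sampled stations inside a forbidden region are removed;
arcs with a smaller overlap are cropped to their longest collision-free run.
The surviving arcs are sparsified across the oblique grid to keep the greedy
search cheap; 1°-shifted oblique neighbors re-densify the space locally
around promising arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Family, sample_arc_angles

MAX_ARC_SPAN_DEG = 80.0


@dataclass(frozen=True)
class Arc:
    """A primary-angle sweep at a fixed oblique tilt in one rotation family."""

    family: Family
    oblique_deg: float
    start_deg: float
    end_deg: float
    step_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.end_deg < self.start_deg:
            raise ValueError("arc end must be >= start")
        if self.span_deg > MAX_ARC_SPAN_DEG + 1e-9:
            raise ValueError(f"arc span {self.span_deg}° exceeds {MAX_ARC_SPAN_DEG}°")
        if self.step_deg <= 0:
            raise ValueError("step must be positive")

    @property
    def span_deg(self) -> float:
        return self.end_deg - self.start_deg

    @property
    def arc_id(self) -> str:
        return (
            f"{self.family.value}/obl{self.oblique_deg:+g}/"
            f"{self.start_deg:+g}..{self.end_deg:+g}"
        )

    def sampled_angles(self) -> np.ndarray:
        return sample_arc_angles(self.start_deg, self.end_deg, self.step_deg)

    @property
    def n_points(self) -> int:
        return len(self.sampled_angles())


@dataclass(frozen=True)
class ForbiddenRegion:
    """An angular rectangle excluded from the orientation sphere."""

    primary_range: tuple[float, float]
    oblique_range: tuple[float, float]
    family_scope: Family | None = None  # None = applies to both families

    def __post_init__(self) -> None:
        if self.primary_range[0] > self.primary_range[1]:
            raise ValueError("primary_range min > max")
        if self.oblique_range[0] > self.oblique_range[1]:
            raise ValueError("oblique_range min > max")

    def applies_to(self, family: Family) -> bool:
        return self.family_scope is None or self.family_scope is family

    def contains(self, primary_deg: np.ndarray, oblique_deg: float) -> np.ndarray:
        p = np.asarray(primary_deg, dtype=float)
        inside_o = self.oblique_range[0] <= oblique_deg <= self.oblique_range[1]
        if not inside_o:
            return np.zeros(p.shape, dtype=bool)
        return (p >= self.primary_range[0]) & (p <= self.primary_range[1])


# Default angular extents.  Each default split spans 79° so that a 1° sampled
# arc has exactly 80 stations and a 4°-stride simulation uses 20 views/arc.
_DEFAULT_SPLITS = {
    Family.RAO_LAO: ((-120.0, -41.0), (-40.0, 39.0), (40.0, 119.0)),
    Family.CRA_CAU: ((-40.0, 39.0),),
}
_DEFAULT_OBLIQUE_RANGE = {
    Family.RAO_LAO: (-60.0, 60.0),
    Family.CRA_CAU: (-90.0, 90.0),
}


@dataclass(frozen=True)
class ArcSpaceConfig:
    """Layout of the initial candidate arc space.

    ``primary_splits`` lists the (start, end) sweep of each arc per family;
    obliques run on a 1° grid over ``oblique_range``.  ``sparsify_spacing_deg``
    keeps only obliques that are multiples of the spacing (anchored at 0°);
    ``forbidden_fraction_threshold`` is the removal cutoff of the
    collision-filtering rule.
    """

    primary_splits: dict = field(default_factory=lambda: dict(_DEFAULT_SPLITS))
    oblique_range: dict = field(default_factory=lambda: dict(_DEFAULT_OBLIQUE_RANGE))
    oblique_step_deg: float = 1.0
    sparsify_spacing_deg: float = 6.0
    forbidden_fraction_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.sparsify_spacing_deg < 1:
            raise ValueError("sparsify spacing must be >= 1 degree")
        if not (0 < self.forbidden_fraction_threshold < 1):
            raise ValueError("forbidden fraction threshold must be in (0, 1)")
        for fam, splits in self.primary_splits.items():
            for lo, hi in splits:
                if hi - lo > MAX_ARC_SPAN_DEG:
                    raise ValueError(
                        f"{fam} split ({lo}, {hi}) exceeds the {MAX_ARC_SPAN_DEG}° cap"
                    )


def build_initial_arcs(config: ArcSpaceConfig) -> list[Arc]:
    """All candidate arcs: per family, per 1°-grid oblique, per primary split.

    Ordering is deterministic: family (RAO/LAO first), then oblique
    ascending, then start angle ascending.
    """
    arcs: list[Arc] = []
    for family in (Family.RAO_LAO, Family.CRA_CAU):
        splits = config.primary_splits.get(family, ())
        if not splits:
            continue
        lo, hi = config.oblique_range[family]
        obliques = sample_arc_angles(lo, hi, config.oblique_step_deg)
        for oblique in obliques:
            for start, end in sorted(splits):
                arcs.append(Arc(family, float(oblique), float(start), float(end)))
    return arcs


def _forbidden_mask(arc: Arc, regions: list[ForbiddenRegion]) -> np.ndarray:
    angles = arc.sampled_angles()
    mask = np.zeros(angles.shape, dtype=bool)
    for region in regions:
        if region.applies_to(arc.family):
            mask |= region.contains(angles, arc.oblique_deg)
    return mask


def forbidden_fraction(arc: Arc, regions: list[ForbiddenRegion]) -> float:
    """Fraction of the arc's sampled stations lying inside any forbidden region."""
    mask = _forbidden_mask(arc, regions)
    return float(mask.mean()) if mask.size else 0.0


def _crop_to_longest_free_run(arc: Arc, mask: np.ndarray) -> Arc | None:
    """Longest contiguous run of collision-free stations, as a new arc."""
    free = ~mask
    if not free.any():
        return None
    # run-length encode the free mask
    padded = np.concatenate(([False], free, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]  # [start, end) index runs
    best = int(np.argmax(ends - starts))
    angles = arc.sampled_angles()
    return replace(
        arc,
        start_deg=float(angles[starts[best]]),
        end_deg=float(angles[ends[best] - 1]),
    )


def filter_and_crop(
    arcs: list[Arc],
    regions: list[ForbiddenRegion],
    threshold: float = 0.10,
) -> list[Arc]:
    """Apply the collision rule: remove arcs with more than ``threshold`` of
    their stations forbidden, crop the rest to their longest free run.

    Every returned arc has zero sampled stations inside any region; with no
    regions the input passes through unchanged.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    out: list[Arc] = []
    for arc in arcs:
        mask = _forbidden_mask(arc, regions)
        frac = float(mask.mean()) if mask.size else 0.0
        if frac == 0.0:
            out.append(arc)
        elif frac <= threshold:
            cropped = _crop_to_longest_free_run(arc, mask)
            if cropped is not None:
                out.append(cropped)
        # frac > threshold: removed
    return out


def sparsify(arcs: list[Arc], spacing_deg: float = 6.0) -> list[Arc]:
    """Keep only arcs whose oblique is a multiple of ``spacing_deg`` (anchor 0°)."""
    if spacing_deg < 1:
        raise ValueError("spacing must be >= 1 degree")
    kept = []
    for arc in arcs:
        r = np.remainder(arc.oblique_deg, spacing_deg)
        if min(r, spacing_deg - r) < 1e-9:
            kept.append(arc)
    return kept


def neighbor_arcs(
    arc: Arc,
    regions: list[ForbiddenRegion],
    threshold: float = 0.10,
    delta_deg: float = 1.0,
    oblique_limits: tuple[float, float] | None = None,
) -> list[Arc]:
    """The (up to two) arcs one oblique step to either side of ``arc``.

    Each neighbor keeps the parent's primary range and is passed through the
    collision filter; neighbors failing the removal rule, or falling outside
    ``oblique_limits``, are omitted.
    """
    if delta_deg < 1:
        raise ValueError("neighbor delta must be >= 1 degree")
    neighbors = []
    for sign in (-1.0, +1.0):
        oblique = arc.oblique_deg + sign * delta_deg
        if oblique_limits is not None and not (
            oblique_limits[0] <= oblique <= oblique_limits[1]
        ):
            continue
        shifted = replace(arc, oblique_deg=oblique)
        neighbors.extend(filter_and_crop([shifted], regions, threshold))
    return neighbors


def arc_records(arcs: list[Arc]) -> list[dict]:
    """CSV/JSON-friendly rows describing each arc."""
    return [
        {
            "id": a.arc_id,
            "family": a.family.value,
            "oblique_deg": a.oblique_deg,
            "start_deg": a.start_deg,
            "end_deg": a.end_deg,
            "n_points": a.n_points,
        }
        for a in arcs
    ]
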