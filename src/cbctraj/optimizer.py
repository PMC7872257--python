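"""Greedy multi-arc trajectory selection with local neighbor refinement.

The search alternates between the two rotation families.  In each round it
scores every arc of the family's sparsified candidate set by simulating the
arc's stride-thinned projections from the prior volume, reconstructing them
together with the projections of all previously selected arcs (ASD-POCS),
and computing the FSIM of the reconstruction against the prior inside the
VOI.  The three best-scoring arcs seed a hill climb: each seed's ±1° oblique
neighbors are generated (re-filtered against the forbidden regions),
evaluated, and expanded further whenever a neighbor improves on its parent.
The best arc seen anywhere joins the trajectory, its projections are added
to the accumulated set, and the next round switches family.

Everything is deterministic: evaluation order is fixed, objective values are
memoized per arc within a round, and ties break by smaller \\|oblique\\|, then
smaller start angle, then family order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .arc_space import (
    Arc,
    ArcSpaceConfig,
    ForbiddenRegion,
    build_initial_arcs,
    filter_and_crop,
    neighbor_arcs,
    sparsify,
)
from .geometry import (
    AnglePair,
    Family,
    GeometryParams,
    pose_from_angles,
    subsample_for_simulation,
)
from .metrics import VOI, FsimConfig, fsim_voi
from .projector import GridSpec, ProjectionStack, Volume, forward_project, hu_to_attenuation
from .recon import ReconParams, asd_pocs


class NoCandidateError(ValueError):
    """No arc survived filtering for the current selection round."""


class TrajectoryIncompleteError(RuntimeError):
    """The target arc count is unreachable; carries the partial trajectory."""

    def __init__(self, message: str, trajectory: "Trajectory", log: "OptimizationResult"):
        super().__init__(message)
        self.trajectory = trajectory
        self.log = log


class RecordStatus(str, Enum):
    EVALUATED = "evaluated"
    REJECTED_FORBIDDEN = "rejected_forbidden"
    PRUNED = "pruned"


@dataclass(frozen=True)
class ObjectiveRecord:
    """Bookkeeping for one candidate-arc evaluation."""

    arc: Arc
    objective: float
    n_projections: int
    rank: int
    status: RecordStatus = RecordStatus.EVALUATED
    step: int = 0

    @property
    def arc_id(self) -> str:
        return self.arc.arc_id


@dataclass
class Trajectory:
    """An ordered multi-arc trajectory with its accumulated angle lists.

    ``sim_angles`` is the stride-thinned list used during optimization;
    ``full_angles`` is the 1°-sampled list an acquisition would execute.
    """

    arcs: list[Arc] = field(default_factory=list)
    sim_angles: list[AnglePair] = field(default_factory=list)
    full_angles: list[AnglePair] = field(default_factory=list)

    def with_arc(self, arc: Arc, sim_stride: int) -> "Trajectory":
        if any(a.arc_id == arc.arc_id for a in self.arcs):
            raise ValueError(f"arc {arc.arc_id} already selected")
        return Trajectory(
            arcs=self.arcs + [arc],
            sim_angles=self.sim_angles + _arc_angle_pairs(arc, sim_stride),
            full_angles=self.full_angles + _arc_angle_pairs(arc, 1),
        )

    @property
    def n_sim_projections(self) -> int:
        return len(self.sim_angles)

    @property
    def n_full_projections(self) -> int:
        return len(self.full_angles)

    @property
    def total_span_deg(self) -> float:
        return float(sum(a.span_deg for a in self.arcs))


def _arc_angle_pairs(arc: Arc, stride: int) -> list[AnglePair]:
    primaries = subsample_for_simulation(arc.sampled_angles(), stride)
    return [AnglePair(arc.family, float(p), arc.oblique_deg) for p in primaries]


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the greedy search.

    ``n_arcs_target`` is the predefined arc count of the final trajectory
    (2 or 3 in typical use); ``seed_count`` the number of top arcs whose
    neighborhoods are explored; ``sim_stride_deg`` the projection thinning
    used for simulation-side reconstructions (4° keeps 20 views per default
    80-station arc, hence 20/40/60 views for 1/2/3-arc states).
    """

    n_arcs_target: int = 3
    family_order: tuple[Family, ...] = (Family.RAO_LAO, Family.CRA_CAU)
    seed_count: int = 3
    neighbor_delta_deg: float = 1.0
    sim_stride_deg: int = 4
    arc_space: ArcSpaceConfig = field(default_factory=ArcSpaceConfig)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    recon: ReconParams = field(default_factory=ReconParams)
    fsim: FsimConfig = field(default_factory=FsimConfig)
    neighbor_move_axis: str = "oblique"  # the sparsified dimension

    def __post_init__(self) -> None:
        if self.n_arcs_target < 1 or self.seed_count < 1:
            raise ValueError("n_arcs_target and seed_count must be >= 1")
        if self.neighbor_move_axis != "oblique":
            raise ValueError("only oblique neighbor moves are implemented")


@dataclass
class OptimizationResult:
    """Complete evaluation log of one optimization run."""

    records: list[ObjectiveRecord] = field(default_factory=list)
    selected_ids: list[str] = field(default_factory=list)
    step_best_objectives: list[float] = field(default_factory=list)

    def records_for_step(self, step: int) -> list[ObjectiveRecord]:
        return [r for r in self.records if r.step == step]


class EvaluationContext:
    """Caches per-orientation projections of the prior across evaluations.

    Candidate arcs overlap heavily with their neighbors, so projections are
    simulated once per (family, primary, oblique) orientation and reused.
    """

    def __init__(self, prior: Volume, cfg: OptimizerConfig, prior_is_hu: bool = True):
        self.prior_mu = hu_to_attenuation(prior) if prior_is_hu else prior
        self.cfg = cfg
        self.grid = GridSpec.of(prior)
        self._cache: dict[tuple, np.ndarray] = {}

    def projection(self, angles: AnglePair) -> np.ndarray:
        key = (angles.family, round(angles.primary_deg, 6), round(angles.oblique_deg, 6))
        if key not in self._cache:
            pose = pose_from_angles(angles, self.cfg.geometry)
            stack = forward_project(
                self.prior_mu, [pose], self.cfg.geometry, self.cfg.recon.step_voxels
            )
            self._cache[key] = stack.images[0]
        return self._cache[key]

    def stack_for(self, angle_list: list[AnglePair]) -> ProjectionStack:
        images = [self.projection(a) for a in angle_list]
        poses = [pose_from_angles(a, self.cfg.geometry) for a in angle_list]
        return ProjectionStack(images, poses, self.cfg.geometry.detector_pixel_pitch_mm)


def evaluate_candidate(
    arc: Arc,
    state: Trajectory,
    prior: Volume,
    voi: VOI,
    cfg: OptimizerConfig,
    context: EvaluationContext | None = None,
    rank: int = 0,
    step: int = 0,
) -> ObjectiveRecord:
    """Objective value of adding ``arc`` to the current trajectory state.

    Simulates the arc's stride-thinned projections from the prior, merges
    them with the state's accumulated simulated projections, reconstructs
    with ASD-POCS and scores the VOI against the prior with FSIM.  ``state``
    is not mutated.  ``prior`` is in Hounsfield units (converted to linear
    attenuation internally); pass a pre-built ``context`` to share the
    projection cache across calls.
    """
    ctx = context or EvaluationContext(prior, cfg)
    angle_list = state.sim_angles + _arc_angle_pairs(arc, cfg.sim_stride_deg)
    stack = ctx.stack_for(angle_list)
    try:
        recon = asd_pocs(stack, ctx.grid, cfg.geometry, cfg.recon)
        score = fsim_voi(ctx.prior_mu, recon, voi, cfg.fsim)
    except Exception as exc:  # noqa: BLE001 - re-raise with provenance
        raise RuntimeError(f"evaluation failed for arc {arc.arc_id}") from exc
    return ObjectiveRecord(arc, score, len(angle_list), rank, RecordStatus.EVALUATED, step)


def _sort_key(cfg: OptimizerConfig):
    order = {fam: i for i, fam in enumerate(cfg.family_order)}

    def key(rec: ObjectiveRecord):
        a = rec.arc
        return (-rec.objective, abs(a.oblique_deg), a.start_deg, order.get(a.family, 99))

    return key


def select_next_arc(
    subset: list[Arc],
    state: Trajectory,
    prior: Volume,
    voi: VOI,
    cfg: OptimizerConfig,
    regions: list[ForbiddenRegion] | None = None,
    context: EvaluationContext | None = None,
    step: int = 0,
) -> tuple[Arc, list[ObjectiveRecord]]:
    """One greedy round: best-``seed_count`` seeding plus 1° hill climbing.

    Every subset arc is evaluated; each of the top seeds spawns ±1° oblique
    neighbors, and lineages keep expanding while a neighbor improves on its
    parent.  Each oblique is evaluated at most once per round.  Returns the
    best arc over everything evaluated, plus the full evaluation log.
    """
    if not subset:
        raise NoCandidateError("empty candidate subset")
    regions = regions or []
    ctx = context or EvaluationContext(prior, cfg)
    threshold = cfg.arc_space.forbidden_fraction_threshold
    records: list[ObjectiveRecord] = []
    memo: dict[tuple, ObjectiveRecord] = {}

    def evaluate(arc: Arc) -> ObjectiveRecord:
        key = (arc.family, arc.oblique_deg, arc.start_deg, arc.end_deg)
        if key not in memo:
            rec = evaluate_candidate(
                arc, state, prior, voi, cfg, ctx, rank=len(records), step=step
            )
            memo[key] = rec
            records.append(rec)
        return memo[key]

    for arc in subset:
        evaluate(arc)
    key_fn = _sort_key(cfg)
    seeds = sorted(records, key=key_fn)[: cfg.seed_count]
    best = seeds[0]

    oblique_limits = cfg.arc_space.oblique_range.get(subset[0].family)
    for seed in seeds:
        frontier = [seed]
        while frontier:
            next_frontier: list[ObjectiveRecord] = []
            for parent in frontier:
                for nb in neighbor_arcs(
                    parent.arc,
                    regions,
                    threshold,
                    cfg.neighbor_delta_deg,
                    oblique_limits,
                ):
                    key = (nb.family, nb.oblique_deg, nb.start_deg, nb.end_deg)
                    seen = key in memo
                    rec = evaluate(nb)
                    if not seen and rec.objective > parent.objective:
                        next_frontier.append(rec)
            frontier = next_frontier
    best = min(records, key=key_fn)
    return best.arc, records


def optimize_trajectory(
    prior: Volume,
    voi: VOI,
    regions: list[ForbiddenRegion] | None = None,
    cfg: OptimizerConfig = OptimizerConfig(),
) -> tuple[Trajectory, OptimizationResult]:
    """Full greedy optimization of an ``n_arcs_target``-arc trajectory.

    Builds the candidate arc space, removes/crops collision arcs, sparsifies
    the oblique grid, then alternates :func:`select_next_arc` rounds over
    the two families, accumulating each winner's simulated projections.

    Raises :class:`TrajectoryIncompleteError` (carrying the partial result)
    if both families run out of candidates before the target count.
    """
    regions = regions or []
    space = sparsify(
        filter_and_crop(
            build_initial_arcs(cfg.arc_space),
            regions,
            cfg.arc_space.forbidden_fraction_threshold,
        ),
        cfg.arc_space.sparsify_spacing_deg,
    )
    ctx = EvaluationContext(prior, cfg)
    state = Trajectory()
    log = OptimizationResult()

    for arc_index in range(cfg.n_arcs_target):
        scheduled = cfg.family_order[arc_index % len(cfg.family_order)]
        families = [scheduled] + [f for f in cfg.family_order if f is not scheduled]
        subset: list[Arc] = []
        for family in families:
            selected = {a.arc_id for a in state.arcs}
            subset = [a for a in space if a.family is family and a.arc_id not in selected]
            if subset:
                break
        if not subset:
            raise TrajectoryIncompleteError(
                f"candidate arcs exhausted after {len(state.arcs)} of "
                f"{cfg.n_arcs_target} arcs",
                state,
                log,
            )
        best_arc, records = select_next_arc(
            subset, state, prior, voi, cfg, regions, ctx, step=arc_index
        )
        log.records.extend(records)
        log.selected_ids.append(best_arc.arc_id)
        log.step_best_objectives.append(
            max(r.objective for r in records if r.status is RecordStatus.EVALUATED)
        )
        state = state.with_arc(best_arc, cfg.sim_stride_deg)
    return state, log
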