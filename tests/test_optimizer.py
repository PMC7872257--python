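"""Greedy trajectory selection: bookkeeping, determinism, optimality."""

import numpy as np
import pytest

import cbctraj as c
from cbctraj.arc_space import Arc
from cbctraj.cli import desk_scale_config
from cbctraj.optimizer import RecordStatus

RAO, CRA = c.Family.RAO_LAO, c.Family.CRA_CAU


@pytest.fixture(scope="module")
def tiny():
    """A 16³ study context: fast enough for many candidate evaluations."""
    run = desk_scale_config(grid=16, n_det=16, oblique_span=2.0)
    import dataclasses

    cfg = dataclasses.replace(
        run.optimizer,
        recon=c.ReconParams(n_outer_iterations=2, tv_descent_steps=5),
    )
    prior = c.make_phantom(run.phantom)
    voi = c.make_voi_targets(run.phantom)[0]
    return {"prior": prior, "voi": voi, "cfg": cfg,
            "ctx": c.EvaluationContext(prior, cfg)}


def default_arc(family=RAO, oblique=0.0, start=-40.0, end=39.0) -> Arc:
    return Arc(family, oblique, start, end)


class TestTrajectoryBookkeeping:
    def test_simulated_views_grow_in_steps_of_20(self):
        traj = c.Trajectory()
        for i, arc in enumerate(
            [default_arc(RAO, 0.0, -120.0, -41.0),
             default_arc(CRA, 0.0, -40.0, 39.0),
             default_arc(RAO, 6.0, 40.0, 119.0)]
        ):
            traj = traj.with_arc(arc, sim_stride=4)
            assert traj.n_sim_projections == 20 * (i + 1)
        assert traj.n_full_projections == 240
        assert traj.total_span_deg == pytest.approx(237.0)

    def test_duplicate_arc_rejected(self):
        traj = c.Trajectory().with_arc(default_arc(), 4)
        with pytest.raises(ValueError):
            traj.with_arc(default_arc(), 4)


class TestEvaluateCandidate:
    def test_first_arc_uses_20_projections(self, tiny):
        rec = c.evaluate_candidate(
            default_arc(), c.Trajectory(), tiny["prior"], tiny["voi"], tiny["cfg"],
            tiny["ctx"],
        )
        assert rec.n_projections == 20
        assert 0.0 < rec.objective <= 1.0
        assert rec.status is RecordStatus.EVALUATED

    def test_second_arc_uses_40_projections(self, tiny):
        state = c.Trajectory().with_arc(default_arc(CRA), 4)
        rec = c.evaluate_candidate(
            default_arc(RAO, 1.0), state, tiny["prior"], tiny["voi"], tiny["cfg"],
            tiny["ctx"],
        )
        assert rec.n_projections == 40

    def test_deterministic_objective(self, tiny):
        args = (default_arc(), c.Trajectory(), tiny["prior"], tiny["voi"], tiny["cfg"],
                tiny["ctx"])
        assert c.evaluate_candidate(*args).objective == c.evaluate_candidate(*args).objective

    def test_state_not_mutated(self, tiny):
        state = c.Trajectory()
        c.evaluate_candidate(
            default_arc(), state, tiny["prior"], tiny["voi"], tiny["cfg"], tiny["ctx"]
        )
        assert state.arcs == [] and state.sim_angles == []


class TestSelectNextArc:
    def test_single_candidate_returned(self, tiny):
        arc = default_arc(RAO, 0.0)
        best, records = c.select_next_arc(
            [arc], c.Trajectory(), tiny["prior"], tiny["voi"], tiny["cfg"],
            context=tiny["ctx"],
        )
        assert best.oblique_deg in (-2.0, -1.0, 0.0, 1.0, 2.0)
        assert any(r.arc.arc_id == arc.arc_id for r in records)

    def test_returned_arc_maximizes_evaluated_objectives(self, tiny):
        subset = [default_arc(RAO, o) for o in (-2.0, 0.0, 2.0)]
        best, records = c.select_next_arc(
            subset, c.Trajectory(), tiny["prior"], tiny["voi"], tiny["cfg"],
            context=tiny["ctx"],
        )
        best_rec = max(records, key=lambda r: r.objective)
        assert best.arc_id == best_rec.arc.arc_id

    def test_empty_subset_raises(self, tiny):
        with pytest.raises(c.NoCandidateError):
            c.select_next_arc(
                [], c.Trajectory(), tiny["prior"], tiny["voi"], tiny["cfg"]
            )

    def test_each_oblique_evaluated_once(self, tiny):
        subset = [default_arc(RAO, o) for o in (-1.0, 0.0, 1.0)]
        _, records = c.select_next_arc(
            subset, c.Trajectory(), tiny["prior"], tiny["voi"], tiny["cfg"],
            context=tiny["ctx"],
        )
        keys = [(r.arc.oblique_deg, r.arc.start_deg) for r in records]
        assert len(keys) == len(set(keys))


@pytest.fixture(scope="module")
def two_arc_run(tiny):
    regions = c.make_forbidden_scenarios()["one"]
    import dataclasses

    cfg = dataclasses.replace(tiny["cfg"], n_arcs_target=2)
    return (
        c.optimize_trajectory(tiny["prior"], tiny["voi"], regions, cfg),
        regions,
        cfg,
    )


class TestOptimizeTrajectory:
    def test_families_alternate(self, two_arc_run):
        (traj, _log), _regions, _cfg = two_arc_run
        assert [a.family for a in traj.arcs] == [RAO, CRA]

    def test_no_selected_arc_touches_forbidden_regions(self, two_arc_run):
        (traj, _log), regions, _cfg = two_arc_run
        for arc in traj.arcs:
            assert c.forbidden_fraction(arc, regions) == 0.0

    def test_log_covers_both_steps_and_best_is_selected(self, two_arc_run):
        (traj, log), _regions, _cfg = two_arc_run
        assert log.selected_ids == [a.arc_id for a in traj.arcs]
        for step in (0, 1):
            recs = log.records_for_step(step)
            assert recs
            best = max(r.objective for r in recs)
            assert log.step_best_objectives[step] == pytest.approx(best)

    def test_greedy_choice_beats_random_alternative(self, two_arc_run, tiny):
        """The second selected arc scores at least as well as a random
        same-family alternative appended to the same first arc."""
        (traj, log), regions, cfg = two_arc_run
        state = c.Trajectory().with_arc(traj.arcs[0], cfg.sim_stride_deg)
        gen = np.random.default_rng(123)
        step2 = [r for r in log.records_for_step(1)]
        alternative = step2[int(gen.integers(len(step2)))]
        assert log.step_best_objectives[1] >= alternative.objective
        del state

    def test_determinism(self, tiny):
        import dataclasses

        cfg = dataclasses.replace(tiny["cfg"], n_arcs_target=1)
        r1 = c.optimize_trajectory(tiny["prior"], tiny["voi"], [], cfg)
        r2 = c.optimize_trajectory(tiny["prior"], tiny["voi"], [], cfg)
        assert [a.arc_id for a in r1[0].arcs] == [a.arc_id for a in r2[0].arcs]
        assert [r.objective for r in r1[1].records] == [
            r.objective for r in r2[1].records
        ]

    def test_exhausted_families_raise_partial_result(self, tiny):
        import dataclasses

        cfg = dataclasses.replace(
            tiny["cfg"],
            n_arcs_target=3,
            arc_space=c.ArcSpaceConfig(
                primary_splits={RAO: ((-40.0, 39.0),)},
                oblique_range={RAO: (0.0, 0.0), CRA: (0.0, 0.0)},
            ),
        )
        with pytest.raises(c.TrajectoryIncompleteError) as err:
            c.optimize_trajectory(tiny["prior"], tiny["voi"], [], cfg)
        assert len(err.value.trajectory.arcs) == 1

    def test_single_arc_space_selects_it(self, tiny):
        import dataclasses

        cfg = dataclasses.replace(
            tiny["cfg"],
            n_arcs_target=1,
            arc_space=c.ArcSpaceConfig(
                primary_splits={RAO: ((-40.0, 39.0),)},
                oblique_range={RAO: (0.0, 0.0), CRA: (0.0, 0.0)},
            ),
        )
        traj, log = c.optimize_trajectory(tiny["prior"], tiny["voi"], [], cfg)
        assert [a.arc_id for a in traj.arcs] == ["RAO_LAO/obl+0/-40..+39"]
        assert len(log.records) >= 1


def test_optimizer_config_validation():
    with pytest.raises(ValueError):
        c.OptimizerConfig(n_arcs_target=0)
    with pytest.raises(ValueError):
        c.OptimizerConfig(neighbor_move_axis="primary")
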