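"""Planner: safe intervals, optimality vs oracle, plan validity, zones."""

import math

import numpy as np
import pytest

from dmfsort.loading import DropletLabel
from dmfsort.sipp import (
    Grid,
    PlanRequest,
    Trajectory,
    ZoneOverflowError,
    assign_goals,
    build_safe_intervals,
    chebyshev,
    default_zones,
    load_instance,
    manhattan,
    plan_all,
    random_instance,
    save_plan,
    sipp_search,
    validate_plan,
)

from conftest import time_expanded_search


class TestSafeIntervals:
    def test_no_obstacles_single_full_interval(self):
        m = build_safe_intervals(Grid(6, 6), [], 1)
        assert m.intervals((3, 4)) == [(0, math.inf)]

    def test_parked_obstacle_blocks_inflated_block_forever(self):
        m = build_safe_intervals(Grid(5, 5), [Trajectory("o", ((2, 2),))], 1)
        for r in range(1, 4):
            for c in range(1, 4):
                assert m.intervals((r, c)) == []
        assert m.intervals((0, 0)) == [(0, math.inf)]
        assert m.intervals((2, 0)) == [(0, math.inf)]

    def test_passing_obstacle_splits_interval(self):
        # obstacle crosses cell (2,3) at t=2 with no inflation
        path = Trajectory("o", ((0, 3), (1, 3), (2, 3), (3, 3), (4, 3)))
        m = build_safe_intervals(Grid(5, 5), [path], 0)
        assert m.intervals((2, 3)) == [(0, 2), (3, math.inf)]

    def test_inflation_uses_chebyshev_distance(self):
        m = build_safe_intervals(Grid(5, 5), [Trajectory("o", ((2, 2),))], 1)
        assert not m.is_safe((1, 1), 0)  # diagonal neighbor inside the ball
        assert m.is_safe((0, 2), 0)


class TestSippSearch:
    def test_empty_grid_attains_manhattan_bound(self):
        m = build_safe_intervals(Grid(5, 5), [], 1)
        traj = sipp_search((0, 0), (4, 4), m)
        assert traj.arrival_time == 8

    def test_goal_inside_inflated_block_infeasible(self):
        m = build_safe_intervals(Grid(5, 5), [Trajectory("o", ((2, 2),))], 1)
        assert sipp_search((0, 0), (2, 3), m) is None

    def test_start_equals_goal(self):
        m = build_safe_intervals(Grid(3, 3), [], 1)
        traj = sipp_search((1, 1), (1, 1), m)
        assert traj.arrival_time == 0 and traj.cells == ((1, 1),)

    def test_corridor_crossing_forces_wait_and_matches_oracle(self):
        # the obstacle sweeps down across the agent's row and parks well
        # clear of it, so the shortest-time plan needs at least one wait
        grid = Grid(5, 7)
        obstacle = Trajectory("o", ((0, 3), (1, 3), (2, 3), (3, 3), (4, 3)))
        m = build_safe_intervals(grid, [obstacle], 1)
        traj = sipp_search((1, 0), (1, 6), m)
        assert traj is not None
        waits = sum(a == b for a, b in zip(traj.cells, traj.cells[1:]))
        assert waits >= 1
        oracle = time_expanded_search(grid, (1, 0), (1, 6), [obstacle], 1, 60)
        assert traj.arrival_time == oracle

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_time_expanded_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        grid = Grid(8, 8)
        # one or two random obstacle walks
        obstacles = []
        for _ in range(int(rng.integers(1, 3))):
            cell = (int(rng.integers(8)), int(rng.integers(8)))
            cells = [cell]
            for _ in range(int(rng.integers(3, 12))):
                nbs = [cell] + list(grid.neighbors(cell))
                cell = nbs[int(rng.integers(len(nbs)))]
                cells.append(cell)
            obstacles.append(Trajectory("o", tuple(cells)))
        m = build_safe_intervals(grid, obstacles, 1)
        start, goal = (0, 0), (7, 7)
        if not m.is_safe(start, 0):
            pytest.skip("random obstacle parked on the start cell")
        traj = sipp_search(start, goal, m, horizon=40)
        oracle = time_expanded_search(grid, start, goal, obstacles, 1, 40)
        if traj is None:
            assert oracle is None
        else:
            assert traj.arrival_time == oracle


class TestPlanAll:
    def test_single_droplet_reduces_to_sipp_search(self):
        grid = Grid(6, 6)
        req = PlanRequest({"a": (0, 0)}, {"a": (5, 5)})
        res = plan_all(req, grid)
        assert res.complete
        m = build_safe_intervals(grid, [], 1)
        assert res.trajectories["a"].arrival_time == sipp_search(
            (0, 0), (5, 5), m
        ).arrival_time

    def test_crossing_pair_valid_and_no_faster_than_solo(self):
        grid = Grid(7, 7)
        req = PlanRequest({"a": (3, 0), "b": (0, 3)}, {"a": (3, 6), "b": (6, 3)})
        res = plan_all(req, grid)
        assert res.complete
        report = validate_plan(res.trajectories, grid, 1)
        assert report.ok
        total = sum(t.arrival_time for t in res.trajectories.values())
        assert total >= manhattan((3, 0), (3, 6)) + manhattan((0, 3), (6, 3))

    def test_starts_at_goals_pure_waits(self):
        req = PlanRequest(
            {"a": (0, 0), "b": (4, 4)}, {"a": (0, 0), "b": (4, 4)}
        )
        res = plan_all(req, Grid(6, 6))
        assert all(t.arrival_time == 0 for t in res.trajectories.values())

    @pytest.mark.parametrize("seed", range(100))
    def test_fuzzed_plans_maintain_safe_gap(self, seed):
        rng = np.random.default_rng(seed)
        rows = int(rng.integers(12, 21))
        cols = int(rng.integers(12, 21))
        n = int(rng.integers(3, 11))
        grid, req = random_instance(rng, rows, cols, n, safe_gap=1)
        res = plan_all(req, grid)
        report = validate_plan(res.trajectories, grid, 1)
        assert report.ok
        if len(res.trajectories) >= 2:
            assert report.min_gap >= 1

    def test_validity_is_priority_order_independent(self):
        rng = np.random.default_rng(77)
        grid, req = random_instance(rng, 10, 10, 4, safe_gap=1)
        ids = sorted(req.starts)
        for perm_seed in range(6):
            order = list(np.random.default_rng(perm_seed).permutation(ids))
            res = plan_all(req, grid, priority=order)
            if res.complete:
                assert validate_plan(res.trajectories, grid, 1).ok

    def test_overlapping_starts_rejected(self):
        with pytest.raises(ValueError):
            PlanRequest({"a": (0, 0), "b": (0, 1)}, {"a": (5, 5), "b": (3, 3)})


class TestValidatePlan:
    def test_parked_with_one_empty_electrode_ok(self):
        trajs = [Trajectory("a", ((0, 0),)), Trajectory("b", ((0, 2),))]
        report = validate_plan(trajs, Grid(4, 4), 1)
        assert report.ok and report.min_gap == 1

    def test_edge_adjacency_is_violation(self):
        trajs = [Trajectory("a", ((0, 0), (0, 1))), Trajectory("b", ((0, 3), (0, 2)))]
        report = validate_plan(trajs, Grid(4, 4), 1)
        assert not report.ok

    def test_head_on_swap_detected_even_without_inflation(self):
        trajs = [Trajectory("a", ((0, 0), (0, 1))), Trajectory("b", ((0, 1), (0, 0)))]
        report = validate_plan(trajs, Grid(4, 4), 0)
        assert not report.ok
        assert any(kind == "swap" for *_, kind in report.violations)


class TestZones:
    def test_single_target_droplet_takes_nearest_east_slot(self):
        grid = Grid(8, 8)
        zones = default_zones(grid)
        goals = assign_goals(
            {"a": (3, 4)}, {"a": DropletLabel.TARGET_ONLY}, zones, grid
        )
        slot = goals["a"]
        assert slot[1] == grid.cols - 1
        assert manhattan((3, 4), slot) == min(
            manhattan((3, 4), s) for s in zones[DropletLabel.TARGET_ONLY]
        )

    def test_same_class_droplets_get_distinct_slots(self):
        grid = Grid(8, 8)
        zones = default_zones(grid)
        goals = assign_goals(
            {"a": (0, 0), "b": (0, 2)},
            {"a": DropletLabel.TARGET_ONLY, "b": DropletLabel.TARGET_ONLY},
            zones,
            grid,
        )
        assert goals["a"] != goals["b"]

    def test_zone_overflow_raises(self):
        zones = {DropletLabel.TARGET_ONLY: [(0, 7)]}
        with pytest.raises(ZoneOverflowError):
            assign_goals(
                {"a": (0, 0), "b": (2, 0)},
                {d: DropletLabel.TARGET_ONLY for d in ("a", "b")},
                zones,
            )

    def test_full_array_assignment_respects_gaps(self, rng):
        # 64 droplets parked on a spacing-2 sub-array of the 128x128 chip
        grid = Grid(128, 128)
        zones = default_zones(grid)
        starts = {
            f"d{r}_{c}": (60 + 2 * r, 60 + 2 * c) for r in range(8) for c in range(8)
        }
        label_pool = list(DropletLabel)
        labels = {
            d: label_pool[int(rng.integers(len(label_pool)))] for d in starts
        }
        goals = assign_goals(starts, labels, zones, grid)
        cells = list(goals.values())
        assert len(set(cells)) == len(cells)
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                assert chebyshev(a, b) >= 2


class TestInstanceIO:
    def test_round_trip(self, tmp_path, rng):
        grid, req = random_instance(rng, 12, 12, 4, safe_gap=1)
        payload = {
            "rows": grid.rows,
            "cols": grid.cols,
            "safe_gap": req.safe_gap,
            "droplets": [
                {"id": d, "start": list(req.starts[d]), "goal": list(req.goals[d])}
                for d in sorted(req.starts)
            ],
        }
        import json

        path = tmp_path / "inst.json"
        path.write_text(json.dumps(payload))
        grid2, req2 = load_instance(path)
        assert grid2 == grid and req2.starts == req.starts and req2.goals == req.goals

        res = plan_all(req2, grid2)
        out = tmp_path / "plan.json"
        save_plan(res, out)
        saved = json.loads(out.read_text())
        assert saved["complete"] == res.complete
        assert set(saved["trajectories"]) == set(res.trajectories)
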