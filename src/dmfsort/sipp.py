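"""Safe Interval Path Planning for droplet routing on the electrode grid.

Droplets on an electrowetting chip merge on contact, so routing must keep
at least one empty electrode between any two droplets at all times — not
merely avoid sharing a cell.  This module implements SIPP (A* over
(cell, safe-interval) states) modified for that contact constraint:

* every dynamic obstacle (an already-planned droplet trajectory) is
  inflated by the safe gap, measured in Chebyshev distance so that
  diagonal adjacency also counts as contact;
* safe intervals per cell are the maximal time windows free of any
  inflated obstacle; an arrived obstacle blocks its goal (inflated)
  forever;
* transitions additionally reject swap/cross conflicts, where the agent
  and an obstacle exchange positions through each other's inflated
  region between two integer timesteps.

Droplets move in discrete time on the 4-connected grid (one electrode per
tick, or wait).  ``plan_all`` routes a set of droplets by prioritised
planning: droplets are planned one at a time, each finished trajectory
becomes a dynamic obstacle, and droplets not yet planned are treated as
obstacles parked at their start cells.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np

from .loading import DropletLabel

__all__ = [
    "Grid",
    "Trajectory",
    "SafeIntervalMap",
    "PlanRequest",
    "PlanResult",
    "ValidationReport",
    "build_safe_intervals",
    "sipp_search",
    "plan_all",
    "validate_plan",
    "assign_goals",
    "default_zones",
    "random_instance",
    "load_instance",
    "save_plan",
    "manhattan",
    "chebyshev",
]

Cell = tuple[int, int]


def manhattan(a: Cell, b: Cell) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


def chebyshev(a: Cell, b: Cell) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


@dataclass(frozen=True)
class Grid:
    """Electrode grid with optional statically blocked cells (0-based)."""

    rows: int
    cols: int
    blocked: frozenset[Cell] = frozenset()

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1 x 1")

    def in_bounds(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.rows and 0 <= c < self.cols

    def passable(self, cell: Cell) -> bool:
        return self.in_bounds(cell) and cell not in self.blocked

    def neighbors(self, cell: Cell):
        r, c = cell
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if self.passable(nb):
                yield nb


@dataclass(frozen=True)
class Trajectory:
    """Timed cell sequence of one droplet; index = integer time.

    The droplet occupies ``cells[t]`` at time ``t`` and holds the final
    cell forever after arrival.  Consecutive cells are identical (wait) or
    4-neighbors (unit move).
    """

    droplet_id: str
    cells: tuple[Cell, ...]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("trajectory needs at least the start cell")
        for a, b in zip(self.cells, self.cells[1:]):
            if manhattan(a, b) > 1:
                raise ValueError(f"illegal step {a} -> {b}")

    @property
    def arrival_time(self) -> int:
        return len(self.cells) - 1

    @property
    def goal(self) -> Cell:
        return self.cells[-1]

    def position(self, t: int) -> Cell:
        return self.cells[min(t, len(self.cells) - 1)]


Interval = tuple[int, float]  # closed-open [start, end); end may be inf


class SafeIntervalMap:
    """Per-cell maximal time intervals free of inflated dynamic obstacles.

    A cell is unsafe at time ``t`` iff some obstacle occupies a cell
    within Chebyshev distance <= ``safe_gap`` at ``t``.  Obstacles block
    their final cell (inflated) for every ``t >=`` their arrival time.
    """

    def __init__(self, grid: Grid, obstacles: list[Trajectory], safe_gap: int = 1):
        if safe_gap < 0:
            raise ValueError("safe gap must be non-negative")
        self.grid = grid
        self.obstacles = list(obstacles)
        self.safe_gap = safe_gap
        self._unsafe: dict[Cell, set[int]] = {}
        self._blocked_from: dict[Cell, int] = {}
        self._cache: dict[Cell, list[Interval]] = {}
        for traj in self.obstacles:
            last = len(traj.cells) - 1
            for t, cell in enumerate(traj.cells):
                for inflated in self._ball(cell):
                    if t == last:
                        prev = self._blocked_from.get(inflated)
                        if prev is None or t < prev:
                            self._blocked_from[inflated] = t
                    else:
                        self._unsafe.setdefault(inflated, set()).add(t)

    def _ball(self, cell: Cell):
        g = self.safe_gap
        r, c = cell
        for dr in range(-g, g + 1):
            for dc in range(-g, g + 1):
                nb = (r + dr, c + dc)
                if self.grid.in_bounds(nb):
                    yield nb

    def intervals(self, cell: Cell) -> list[Interval]:
        """Sorted disjoint safe intervals of ``cell`` (possibly empty)."""
        cached = self._cache.get(cell)
        if cached is not None:
            return cached
        blocked_from = self._blocked_from.get(cell, math.inf)
        unsafe = sorted(t for t in self._unsafe.get(cell, ()) if t < blocked_from)
        out: list[Interval] = []
        start = 0
        for t in unsafe:
            if t > start:
                out.append((start, t))
            start = t + 1
        if start < blocked_from:
            out.append((start, blocked_from))
        self._cache[cell] = out
        return out

    def is_safe(self, cell: Cell, t: int) -> bool:
        if t >= self._blocked_from.get(cell, math.inf):
            return False
        return t not in self._unsafe.get(cell, ())

    def move_ok(self, src: Cell, dst: Cell, depart: int) -> bool:
        """Reject transitions that swap/cross through an inflated obstacle.

        Vertex safety at the endpoints is handled by the intervals; this
        checks the transition ``src@depart -> dst@depart+1`` against each
        obstacle's simultaneous move.
        """
        g = self.safe_gap
        for traj in self.obstacles:
            o0 = traj.position(depart)
            o1 = traj.position(depart + 1)
            if o0 == o1:
                continue
            if chebyshev(dst, o0) <= g and chebyshev(src, o1) <= g:
                return False
        return True


def build_safe_intervals(
    grid: Grid, obstacles: list[Trajectory], safe_gap: int = 1
) -> SafeIntervalMap:
    """Construct the safe-interval map for a set of obstacle trajectories."""
    return SafeIntervalMap(grid, obstacles, safe_gap)


def sipp_search(
    start: Cell,
    goal: Cell,
    intervals: SafeIntervalMap,
    horizon: int | None = None,
    droplet_id: str = "",
) -> Trajectory | None:
    """Earliest-arrival single-droplet search over safe intervals.

    A* over (cell, interval) states with the Manhattan-distance heuristic
    (moves are 4-connected unit steps, so Manhattan distance lower-bounds
    the arrival time).  Waiting is implicit: a state covers every
    departure time inside its interval.  The goal must be reached inside
    an interval that extends to infinity, because the droplet parks there
    forever.  Returns ``None`` when no trajectory exists within the
    horizon (infeasibility is a result, not an exception).
    """
    grid = intervals.grid
    if not grid.passable(start) or not grid.passable(goal):
        return None
    if horizon is None:
        horizon = 4 * (grid.rows + grid.cols) + max(
            (len(o.cells) for o in intervals.obstacles), default=0
        )

    start_ivs = intervals.intervals(start)
    start_idx = next((i for i, (s, e) in enumerate(start_ivs) if s <= 0 < e), None)
    if start_idx is None:
        return None

    # state = (cell, interval index); g_best = earliest known arrival time
    g_best: dict[tuple[Cell, int], float] = {(start, start_idx): 0}
    parent: dict[tuple[Cell, int], tuple[Cell, int]] = {}
    tie = itertools.count()
    heap: list[tuple[int, int, int, Cell, int]] = [
        (manhattan(start, goal), 0, next(tie), start, start_idx)
    ]

    while heap:
        _, g, _, cell, idx = heappop(heap)
        state = (cell, idx)
        if g_best.get(state, math.inf) < g:
            continue  # stale entry
        _, iv_end = intervals.intervals(cell)[idx]
        if cell == goal and iv_end == math.inf:
            return _reconstruct(droplet_id, state, parent, g_best)
        for nb in grid.neighbors(cell):
            for nb_idx, (s2, e2) in enumerate(intervals.intervals(nb)):
                lo = max(g + 1, s2)
                hi = min(iv_end, e2 - 1, horizon)  # depart <= iv_end - 1
                t = lo
                while t <= hi and not intervals.move_ok(cell, nb, t - 1):
                    t += 1
                if t > hi:
                    continue
                key = (nb, nb_idx)
                if t < g_best.get(key, math.inf):
                    g_best[key] = t
                    parent[key] = state
                    heappush(heap, (t + manhattan(nb, goal), t, next(tie), nb, nb_idx))
    return None


def _reconstruct(
    droplet_id: str,
    goal_state: tuple[Cell, int],
    parent: dict[tuple[Cell, int], tuple[Cell, int]],
    g_best: dict[tuple[Cell, int], float],
) -> Trajectory:
    chain: list[tuple[Cell, int]] = []  # (cell, arrival time), goal -> start
    state = goal_state
    while True:
        chain.append((state[0], int(g_best[state])))
        if state not in parent:
            break
        state = parent[state]
    chain.reverse()
    cells: list[Cell] = []
    for i, (cell, t_in) in enumerate(chain):
        if i + 1 < len(chain):
            t_next = chain[i + 1][1]
            cells.extend([cell] * (t_next - t_in))  # wait, then hop
        else:
            cells.append(cell)
    return Trajectory(droplet_id, tuple(cells))


@dataclass(frozen=True)
class PlanRequest:
    """Starts, goals and routing parameters for a set of droplets."""

    starts: dict[str, Cell]
    goals: dict[str, Cell]
    safe_gap: int = 1
    horizon: int | None = None

    def __post_init__(self) -> None:
        if set(self.starts) != set(self.goals):
            raise ValueError("starts and goals must cover the same droplet ids")
        for name, cells in (("starts", self.starts), ("goals", self.goals)):
            for (a, pa), (b, pb) in itertools.combinations(cells.items(), 2):
                if chebyshev(pa, pb) <= self.safe_gap:
                    raise ValueError(
                        f"{name} of droplets {a!r} and {b!r} violate the safe gap"
                    )


@dataclass
class PlanResult:
    """Outcome of prioritised planning: trajectories plus any failures."""

    trajectories: dict[str, Trajectory]
    infeasible: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.infeasible


def plan_all(
    request: PlanRequest,
    grid: Grid,
    priority: list[str] | None = None,
) -> PlanResult:
    """Prioritised SIPP planning for every droplet in the request.

    Droplets are planned sequentially; each planned trajectory becomes a
    dynamic obstacle for the searches that follow, and droplets not yet
    planned count as obstacles parked at their start cells.  The default
    priority is ascending Manhattan distance to goal, ties broken by
    droplet id.  An infeasible droplet is reported (and left parked as an
    obstacle) rather than aborting the whole plan.
    """
    ids = list(request.starts)
    for d in ids:
        if not grid.passable(request.starts[d]) or not grid.passable(request.goals[d]):
            raise ValueError(f"droplet {d!r} has a start or goal off the grid")
    if priority is None:
        priority = sorted(
            ids, key=lambda d: (manhattan(request.starts[d], request.goals[d]), d)
        )
    elif sorted(priority) != sorted(ids):
        raise ValueError("priority must be a permutation of the droplet ids")

    planned: dict[str, Trajectory] = {}
    infeasible: list[str] = []
    for pos, d in enumerate(priority):
        parked = [
            Trajectory(other, (request.starts[other],))
            for other in priority[pos + 1 :]
        ] + [Trajectory(other, (request.starts[other],)) for other in infeasible]
        simap = build_safe_intervals(
            grid, list(planned.values()) + parked, request.safe_gap
        )
        traj = sipp_search(
            request.starts[d], request.goals[d], simap, request.horizon, droplet_id=d
        )
        if traj is None:
            infeasible.append(d)
        else:
            planned[d] = traj
    return PlanResult(planned, infeasible)


@dataclass
class ValidationReport:
    """Pairwise clearance audit of a set of trajectories."""

    ok: bool
    violations: list[tuple[int, str, str, str]]  # (time, id, id, kind)
    min_separation: float  # min pairwise Chebyshev distance over all times

    @property
    def min_gap(self) -> float:
        """Empty electrodes maintained between the closest pair ever seen."""
        return self.min_separation - 1


def validate_plan(
    trajectories: dict[str, Trajectory] | list[Trajectory],
    grid: Grid,
    safe_gap: int = 1,
) -> ValidationReport:
    """Check a plan for clearance and swap/cross conflicts at all times.

    Trajectories are padded at their goals; at every integer time all
    pairwise Chebyshev distances must exceed ``safe_gap``, and between
    consecutive times no pair may exchange positions through each other's
    inflated region.
    """
    trajs = (
        list(trajectories.values())
        if isinstance(trajectories, dict)
        else list(trajectories)
    )
    for traj in trajs:
        for cell in traj.cells:
            if not grid.passable(cell):
                raise ValueError(
                    f"trajectory {traj.droplet_id!r} leaves the grid at {cell}"
                )
    horizon = max((t.arrival_time for t in trajs), default=0)
    violations: list[tuple[int, str, str, str]] = []
    min_sep = math.inf
    for a, b in itertools.combinations(trajs, 2):
        for t in range(horizon + 1):
            pa, pb = a.position(t), b.position(t)
            d = chebyshev(pa, pb)
            min_sep = min(min_sep, d)
            if d <= safe_gap:
                violations.append((t, a.droplet_id, b.droplet_id, "proximity"))
            if t < horizon:
                pa1, pb1 = a.position(t + 1), b.position(t + 1)
                if (
                    pa != pa1
                    and pb != pb1
                    and chebyshev(pa1, pb) <= safe_gap
                    and chebyshev(pa, pb1) <= safe_gap
                ):
                    violations.append((t, a.droplet_id, b.droplet_id, "swap"))
    return ValidationReport(not violations, violations, min_sep)


class ZoneOverflowError(RuntimeError):
    """A label class has more droplets than free zone slots."""


def default_zones(grid: Grid, spacing: int = 2) -> dict[DropletLabel, list[Cell]]:
    """Default sorting zones: collect east, waste west, park mixed centrally.

    Slots within each zone are spaced ``spacing`` electrodes apart so any
    assignment of droplets to slots respects a safe gap of
    ``spacing - 1``.  Predicted-empty droplets share the waste zone.
    """
    rows = list(range(0, grid.rows, spacing))
    collect = [(r, grid.cols - 1) for r in rows]
    waste = [(r, 0) for r in rows]
    park_cols = list(range(spacing, grid.cols - spacing, spacing))
    park = [(r, c) for r in rows for c in park_cols]
    return {
        DropletLabel.TARGET_ONLY: collect,
        DropletLabel.BACKGROUND_ONLY: waste,
        DropletLabel.EMPTY: waste,
        DropletLabel.MIXED: park,
    }


def assign_goals(
    starts: dict[str, Cell],
    labels: dict[str, DropletLabel],
    zones: dict[DropletLabel, list[Cell]],
    grid: Grid | None = None,
) -> dict[str, Cell]:
    """Deterministically map labelled droplets to zone slots.

    Droplets are processed in ascending id order; each takes the nearest
    (Manhattan) free slot of its class zone, ties broken by the slot's
    row-major position.  Classes sharing a zone (waste) share its slots.
    """
    if set(starts) != set(labels):
        raise ValueError("starts and labels must cover the same droplet ids")
    used: set[Cell] = set()
    goals: dict[str, Cell] = {}
    for d in sorted(starts):
        slots = zones.get(labels[d], [])
        if grid is not None:
            slots = [s for s in slots if grid.passable(s)]
        free = [s for s in slots if s not in used]
        if not free:
            raise ZoneOverflowError(
                f"no free slot left in the {labels[d].value} zone for droplet {d!r}"
            )
        best = min(free, key=lambda s: (manhattan(starts[d], s), s))
        used.add(best)
        goals[d] = best
    return goals


def random_instance(
    rng: np.random.Generator,
    rows: int,
    cols: int,
    n_droplets: int,
    safe_gap: int = 1,
) -> tuple[Grid, PlanRequest]:
    """Random feasible-by-construction planner instance.

    Starts are mutually separated by more than ``safe_gap``, as are goals,
    and every goal also clears every other droplet's start so parked
    not-yet-planned droplets do not sit on anyone's goal.
    """
    grid = Grid(rows, cols)

    def _sample(avoid: list[Cell], also_clear: list[Cell]) -> Cell:
        for _ in range(10_000):
            cell = (int(rng.integers(rows)), int(rng.integers(cols)))
            if all(chebyshev(cell, o) > safe_gap for o in avoid + also_clear):
                return cell
        raise RuntimeError("could not place droplets with the requested gap")

    starts: list[Cell] = []
    for _ in range(n_droplets):
        starts.append(_sample(starts, []))
    goals: list[Cell] = []
    for i in range(n_droplets):
        other_starts = [s for j, s in enumerate(starts) if j != i]
        goals.append(_sample(goals, other_starts))
    ids = [f"d{i}" for i in range(n_droplets)]
    return grid, PlanRequest(
        dict(zip(ids, starts)), dict(zip(ids, goals)), safe_gap=safe_gap
    )


def load_instance(path) -> tuple[Grid, PlanRequest]:
    """Read a planner instance from JSON (grid, droplets, safe gap)."""
    with open(path) as fh:
        data = json.load(fh)
    grid = Grid(
        int(data["rows"]),
        int(data["cols"]),
        frozenset(tuple(c) for c in data.get("blocked", [])),
    )
    starts = {d["id"]: tuple(d["start"]) for d in data["droplets"]}
    goals = {d["id"]: tuple(d["goal"]) for d in data["droplets"]}
    request = PlanRequest(
        starts,
        goals,
        safe_gap=int(data.get("safe_gap", 1)),
        horizon=data.get("horizon"),
    )
    return grid, request


def save_plan(result: PlanResult, path) -> None:
    """Write a plan as JSON: per-droplet timed cell lists plus failures."""
    payload = {
        "complete": result.complete,
        "infeasible": result.infeasible,
        "trajectories": {
            d: [list(c) for c in traj.cells]
            for d, traj in result.trajectories.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
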