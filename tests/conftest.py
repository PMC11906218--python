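"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest
from scipy import stats

from dmfsort.sipp import Grid, Trajectory, chebyshev


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def expected_collected_per_droplet(
    lambda_target: float, lambda_background: float, precision: float, kmax: int = 40
) -> tuple[float, float]:
    """Brute-force one-cycle expectation of collected objects per droplet.

    Sums, over truncated Poisson supports, the probability that a droplet
    with (h, b) objects is predicted target-only — all h targets read
    correctly and all b background objects misread — times its true
    contents.  Independent of the simulator's sampling path.
    """
    ph = stats.poisson.pmf(np.arange(kmax), lambda_target)
    pb = stats.poisson.pmf(np.arange(kmax), lambda_background)
    e_target = 0.0
    e_background = 0.0
    for h in range(kmax):
        for b in range(kmax):
            if h + b == 0:
                continue
            p_collect = precision**h * (1 - precision) ** b
            w = ph[h] * pb[b] * p_collect
            e_target += w * h
            e_background += w * b
    return e_target, e_background


def time_expanded_search(
    grid: Grid,
    start: tuple[int, int],
    goal: tuple[int, int],
    obstacles: list[Trajectory],
    safe_gap: int,
    horizon: int,
) -> int | None:
    """Earliest feasible arrival by BFS over the time-expanded graph.

    Explicitly enumerates (cell, time) states with wait and 4-neighbor
    moves, vertex clearance against inflated obstacles, swap/cross edge
    checks, and the requirement that the goal stay clear forever after
    arrival (obstacles are static once arrived).  Serves as the optimality
    oracle for the interval-based search on small instances.
    """

    def pos(traj: Trajectory, t: int) -> tuple[int, int]:
        return traj.cells[min(t, len(traj.cells) - 1)]

    def safe(cell: tuple[int, int], t: int) -> bool:
        return all(chebyshev(cell, pos(o, t)) > safe_gap for o in obstacles)

    static_from = max((len(o.cells) - 1 for o in obstacles), default=0)
    if not grid.passable(start) or not grid.passable(goal) or not safe(start, 0):
        return None
    seen = {(start, 0)}
    queue: deque[tuple[tuple[int, int], int]] = deque([(start, 0)])
    while queue:
        cell, t = queue.popleft()
        if cell == goal and all(safe(goal, tt) for tt in range(t, static_from + 1)):
            return t
        if t >= horizon:
            continue
        for nb in [cell, *grid.neighbors(cell)]:
            if not safe(nb, t + 1):
                continue
            if any(
                pos(o, t) != pos(o, t + 1)
                and chebyshev(nb, pos(o, t)) <= safe_gap
                and chebyshev(cell, pos(o, t + 1)) <= safe_gap
                for o in obstacles
            ):
                continue
            if (nb, t + 1) not in seen:
                seen.add((nb, t + 1))
                queue.append((nb, t + 1))
    return None
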