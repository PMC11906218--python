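"""Iterative sort-collect-replenish cycle engine.

One sorting cycle on the droplet array:

1. every droplet is read by the (virtual) classifier;
2. fates are applied by predicted label — predicted target-only droplets
   are collected, predicted background-only and predicted empty droplets
   are sent to waste, predicted mixed droplets are retained on chip;
3. the retained droplets are merged with fresh empty droplets (pure
   diluent: they carry no objects) to rebuild the full array;
4. the pooled objects are re-split: each retained object lands in one of
   the ``n_droplets`` new droplets uniformly at random;
5. the occupancy means are recomputed as retained objects per droplet.

Because the diluent droplets are empty, the occupancy mean shrinks every
cycle, mixed droplets become rarer, and repeated cycles recover target
cells that were initially locked inside mixed droplets.  Recovery is the
fraction of all target cells collected; purity is the target fraction of
everything collected.  Misreads are redrawn independently every cycle.
Targets lost to waste (a droplet whose objects are all misread is routed
by its predicted label) are what caps the recovery below one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .classifier import ClassifierSpec, detect_array
from .loading import DropletArray, DropletLabel, LoadingSpec, sample_array

__all__ = [
    "Fate",
    "SortingPolicy",
    "SortingState",
    "SortingMetrics",
    "init_state",
    "run_cycle",
    "metrics",
    "run_sorting",
    "replicate_rngs",
]

Fate = Literal["collect", "waste", "retain"]

DEFAULT_FATES: dict[DropletLabel, Fate] = {
    DropletLabel.TARGET_ONLY: "collect",
    DropletLabel.BACKGROUND_ONLY: "waste",
    DropletLabel.EMPTY: "waste",
    DropletLabel.MIXED: "retain",
}

#: Fate map for a pre-sorting pass: the abundant background class is pulled
#: out (to waste) while anything that may hold a target stays on chip.
PRESORT_FATES: dict[DropletLabel, Fate] = {
    DropletLabel.TARGET_ONLY: "retain",
    DropletLabel.BACKGROUND_ONLY: "waste",
    DropletLabel.EMPTY: "waste",
    DropletLabel.MIXED: "retain",
}


@dataclass(frozen=True)
class SortingPolicy:
    """Array size, cycle count and the predicted-label -> fate map."""

    n_droplets: int = 64
    n_cycles: int = 3
    fates: dict[DropletLabel, Fate] = field(
        default_factory=lambda: dict(DEFAULT_FATES)
    )

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("need at least one droplet")
        if self.n_cycles < 0:
            raise ValueError("cycle count must be non-negative")
        if set(self.fates) != set(DropletLabel):
            raise ValueError("fate map must cover every predicted label exactly once")
        for fate in self.fates.values():
            if fate not in ("collect", "waste", "retain"):
                raise ValueError(f"unknown fate {fate!r}")


@dataclass
class SortingState:
    """Droplets on chip plus cumulative tallies (exact integer accounting)."""

    cycle_index: int
    droplets: DropletArray
    collected_target: int
    collected_background: int
    wasted_target: int
    wasted_background: int
    initial_target: int
    initial_background: int
    lambda_history: list[tuple[float, float]]

    def check_conservation(self) -> None:
        """Every object is on chip, collected, or wasted — never lost."""
        on_chip_t = self.droplets.total_target
        on_chip_b = self.droplets.total_background
        if self.collected_target + self.wasted_target + on_chip_t != self.initial_target:
            raise RuntimeError("target-object conservation violated")
        if (
            self.collected_background + self.wasted_background + on_chip_b
            != self.initial_background
        ):
            raise RuntimeError("background-object conservation violated")


@dataclass(frozen=True)
class SortingMetrics:
    """Recovery and purity of the cumulative collection.

    ``purity`` is ``None`` while nothing has been collected; ``recovery``
    is ``None`` when the sample held no target at all.
    """

    recovery: float | None
    purity: float | None


def init_state(
    spec: LoadingSpec, policy: SortingPolicy, rng: np.random.Generator
) -> SortingState:
    """Sample the initial array and record the ground-truth totals."""
    array = sample_array(spec, policy.n_droplets, rng)
    n = policy.n_droplets
    return SortingState(
        cycle_index=0,
        droplets=array,
        collected_target=0,
        collected_background=0,
        wasted_target=0,
        wasted_background=0,
        initial_target=array.total_target,
        initial_background=array.total_background,
        lambda_history=[(array.total_target / n, array.total_background / n)],
    )


def _resplit(total: int, n_droplets: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform redistribution of pooled objects over the rebuilt array."""
    return rng.multinomial(total, np.full(n_droplets, 1.0 / n_droplets))


def run_cycle(
    state: SortingState,
    classifier: ClassifierSpec,
    policy: SortingPolicy,
    rng: np.random.Generator,
) -> SortingState:
    """Run one classify / route / replenish / re-split cycle."""
    state.check_conservation()
    _, _, labels = detect_array(state.droplets, classifier, rng)
    fates = np.array([policy.fates[lab] for lab in labels])

    collect = fates == "collect"
    waste = fates == "waste"
    retain = fates == "retain"

    nt, nb = state.droplets.n_target, state.droplets.n_background
    retained_t = int(nt[retain].sum())
    retained_b = int(nb[retain].sum())

    n = policy.n_droplets
    new_state = replace(
        state,
        cycle_index=state.cycle_index + 1,
        droplets=DropletArray(
            _resplit(retained_t, n, rng), _resplit(retained_b, n, rng)
        ),
        collected_target=state.collected_target + int(nt[collect].sum()),
        collected_background=state.collected_background + int(nb[collect].sum()),
        wasted_target=state.wasted_target + int(nt[waste].sum()),
        wasted_background=state.wasted_background + int(nb[waste].sum()),
        lambda_history=state.lambda_history + [(retained_t / n, retained_b / n)],
    )
    new_state.check_conservation()
    return new_state


def metrics(state: SortingState) -> SortingMetrics:
    """Cumulative recovery and purity of the collection so far."""
    state.check_conservation()
    recovery = (
        None
        if state.initial_target == 0
        else state.collected_target / state.initial_target
    )
    n_collected = state.collected_target + state.collected_background
    purity = None if n_collected == 0 else state.collected_target / n_collected
    return SortingMetrics(recovery, purity)


def replicate_rngs(root_seed: int, n_replicates: int) -> list[np.random.Generator]:
    """Independent child streams, one per replicate, from a single root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(root_seed).spawn(n_replicates)]


def run_sorting(
    spec: LoadingSpec,
    classifier: ClassifierSpec,
    policy: SortingPolicy,
    n_replicates: int,
    root_seed: int,
) -> pd.DataFrame:
    """Run replicated sorting and tabulate per-cycle cumulative metrics.

    Returns a tidy frame with one row per (replicate, cycle): recovery,
    purity (NaN while nothing collected), the recomputed occupancy means
    and the cumulative collected counts.  Fully determined by
    ``root_seed``; replicate ``i`` consumes its own child stream.
    """
    rows = []
    for rep, rng in enumerate(replicate_rngs(root_seed, n_replicates)):
        state = init_state(spec, policy, rng)
        for _ in range(policy.n_cycles):
            state = run_cycle(state, classifier, policy, rng)
            m = metrics(state)
            lam_t, lam_b = state.lambda_history[-1]
            rows.append(
                {
                    "replicate": rep,
                    "cycle": state.cycle_index,
                    "recovery": np.nan if m.recovery is None else m.recovery,
                    "purity": np.nan if m.purity is None else m.purity,
                    "lambda_target": lam_t,
                    "lambda_background": lam_b,
                    "collected_target": state.collected_target,
                    "collected_background": state.collected_background,
                }
            )
    return pd.DataFrame(rows)
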