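# Methods

## Droplet loading model

Droplet occupancy follows the standard dilute-suspension model: splitting
a well-mixed sample into droplets of volume `V` at number concentration
`C` gives i.i.d. Poisson counts with mean `λ = C·V`. The default chip
geometry is a 250 µm electrode pitch with a 50 µm plate gap, so each
droplet occupies `250² × 50 µm³ = 3.125 nL` and the default 8 × 8 array
totals 0.2 µL. We resolve the per-droplet/array-total volume ambiguity in
favor of 3.125 nL per droplet because only that reading reproduces λ = 1
at the reference loading of 3.2 × 10⁵ cells/mL.

For a two-species mixture the target and background counts are
independent Poissons. The target:background ratio ρ parameterises the
background mean as `λ_B = λ_T/ρ`, with λ_T fixed at 1 in the ratio
studies. The ratio-sweep grid is 20 uniformly spaced values from 5.0 down
to 0.5 (step ≈ 0.237); the endpoints and count are the study conditions,
the uniform spacing is our choice since nothing else pins it down.

### Goodness of fit

`poisson_gof` estimates λ by the sample mean (the Poisson MLE), bins
occupancies at 0, 1, 2, … and pools the right tail so every expected bin
count is ≥ 5, then refers the χ² statistic to `#bins − 2` degrees of
freedom (one for normalisation, one for the estimated mean). Samples that
cannot support this — fewer than two droplets, an all-zero sample, or
fewer than three usable bins — raise `DegenerateDataError` rather than
returning a meaningless p-value. Low-occupancy bins are not pooled; the
test is intended for the dilute regime (λ ≲ 3) where the head bins are
well populated. A discrete Kolmogorov–Smirnov variant (`poisson_ks`)
computes the sup-distance on the integer support; its Kolmogorov p-value
is conservative for discrete data with an estimated mean, so it is a
companion diagnostic only.

## Virtual classifier

The object detector is modelled purely as a per-object class channel:
every object is detected (recall 1, no spurious detections on empty
droplets), and each object independently keeps its true class with
probability `precision`, flipping to the other class otherwise. The
confusion is symmetric with one shared precision by default, matching a
detector characterised by a single precision figure; per-class precisions
are accepted for asymmetric detectors. The droplet-level predicted label
applies the same rule as true labelling to the predicted counts, so a
droplet is predicted target-only — and collected — only when *every*
object in it is read as a target: `p^h (1 − p)^b` for contents (h, b).
This closed form (`collection_probability`) is the analytic oracle the
simulator is tested against.

## Sorting-cycle engine

Per cycle: classify every droplet; collect predicted target-only
droplets; waste predicted background-only **and predicted empty**
droplets; retain predicted mixed droplets; pool the retained droplets
with fresh empty diluent droplets to rebuild the array; re-split; update
the occupancy means as retained objects per droplet. Wasting predicted
empties is a design choice — the alternative (retaining them) is a
one-line fate-map override in the config — chosen because it keeps the
dilution bookkeeping transparent: every droplet leaving the system exits
through an explicit tally, and conservation
(`collected + wasted + on-chip = initial`, exactly, per species) is
asserted every cycle.

Re-splitting is modelled as a uniform multinomial redistribution of the
pooled objects over the rebuilt array; the physical one-to-two splitting
cascade is not simulated geometrically, but its end state — each object
landing in one of n droplets uniformly and independently — is the same
under well-mixed merging. Misreads are redrawn independently every cycle
(classification noise has no per-object memory). A droplet whose objects
are all misread is routed by its predicted label, true contents and all;
targets wasted this way are what cap recovery below one.

Recovery is `collected_target / initial_target`; purity is
`collected_target / (collected_target + collected_background)`. When
nothing has been collected, purity is reported as missing (`None`/NaN),
not zero, so replicate means are not biased downward; recovery is
likewise missing for a sample that contained no target.

Replication: each experiment consumes one root seed; replicate *i* runs
on an independent child stream spawned from it, so any table cell can be
regenerated in isolation and whole studies are bit-reproducible.

## Pre-sorting for rare targets

When targets are rare (ρ < 1) most droplets are background-only and a
single pass recovers little. The pre-sorting pass swaps the species
roles: predicted background-only droplets are pulled out to waste,
everything that may hold a target (predicted target-only or mixed) is
retained, diluted and re-split; the occupancy means after the pass are
recomputed from the actual retained counts, exactly as in the cycle
engine. This raises the target:background ratio before the ordinary
target sort runs. The default comparison pairs both arms on the same
initial array per replicate, at ratio 0.25 and one sorting cycle each.

## Droplet path planning

Droplets merge on contact through surface tension, so the routing
constraint is a safe *distance*, not mere cell-disjointness: with the
default `safe_gap = 1` (one empty electrode), droplet centers must keep
Chebyshev distance ≥ 2 at every timestep. Chebyshev rather than Manhattan
is the deliberate, stricter reading: diagonal adjacency also risks
merging. Time is discrete (one 4-connected move or wait per tick), each
droplet occupies one electrode, and the routing grid defaults to the
chip's 128 × 128 electrode array.

`sipp_search` is A* over (cell, safe-interval) states with the Manhattan
heuristic. Safe intervals are the maximal time windows in which a cell is
clear of every obstacle inflated by the safe gap; an arrived obstacle
blocks its goal (inflated) forever, and a goal is only accepted in an
interval extending to infinity, since the droplet parks there.
Transitions are additionally rejected when the agent and an obstacle
would exchange positions through each other's inflated region between
two integer times (swap/cross conflicts, which vertex checks alone miss
at `safe_gap = 0`). Infeasibility is returned as a value, not raised.

`plan_all` is prioritized planning: droplets are planned in ascending
Manhattan-distance order (ties by id — a common heuristic; nothing in the
problem fixes the order), each finished trajectory becomes a dynamic
obstacle, and droplets not yet planned count as obstacles parked at their
starts. Validity of the combined plan is order-independent (each pair is
separated by whichever member planned later); cost is not.
`validate_plan` audits any plan independently of the planner: pairwise
clearance at every integer time plus the swap/cross check.

Goal assignment (`assign_goals`) is deterministic: droplets in ascending
id order each take the nearest (Manhattan) free slot of their class zone,
ties broken row-major. Default zones put collection slots on the east
edge, waste on the west edge and mixed-droplet parking in the center,
all spaced two electrodes so any assignment respects the gap.

## Synthetic data and what the tests show

Everything here is simulation: generated droplet arrays, a stochastic
classifier, and randomly generated routing instances. The defaults are
the study conditions throughout — 64 droplets, λ_T = λ_B = 1, precision
0.985 for the cycle study (0.9 for the ratio sweep), 10 replicates,
20-point sweep grids, safe gap 1. What the model deliberately omits:
droplet-volume shortfalls during replenishment, occasional manipulation
failures of the chip, position-dependent detection errors (objects at the
droplet edge), and any correlation of misreads across cycles. Passing
tests therefore validate the statistical machinery and the planner, and
set an upper bound on what the physical workflow achieves — on-chip
recovery and purity run slightly below these simulations, and on-chip
purity drifts down slowly with cycle count, which the memoryless
classifier cannot reproduce.

## Problem sizes and numerics

Monte-Carlo checks use 10⁶ droplets for type-frequency agreement (within
4 binomial standard errors), 10⁵ trials for per-droplet misread rates,
10⁴ droplets for the one-cycle analytic-oracle comparison, and 1000
64-droplet arrays for occupancy-mean recovery (|mean λ̂ − 1| < 0.02).
Planner fuzzing uses 100 random instances on 12 × 12 to 20 × 20 grids
with 3–10 droplets, cross-checked against a time-expanded BFS oracle on
≤ 8 × 8 instances. Closed-form proportions are exact to 1e-12
normalisation; concentration↔λ round-trips hold to relative 1e-12.
Search ties in A* are broken by insertion order; the default search
horizon is `4·(rows + cols)` plus the longest obstacle trajectory.
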