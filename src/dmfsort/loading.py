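"""Poisson statistics of droplet loading on the electrode array.

When a cell suspension is split into an array of nanoliter droplets, the
number of cells captured per droplet is Poisson distributed with mean
``lambda = concentration x droplet_volume``.  For a two-species mixture
(target cells vs. background objects) the per-droplet counts of the two
species are independent Poissons, so the probabilities of the four droplet
types (empty, target-only, background-only, mixed) have simple closed
forms.  This module provides the unit conversions between concentration and
occupancy mean, samplers for droplet arrays, droplet typing, the
closed-form type proportions, and goodness-of-fit tests for observed
occupancy counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChipGeometry",
    "LoadingSpec",
    "DropletArray",
    "DropletContents",
    "DropletLabel",
    "GofResult",
    "droplet_volume",
    "lambda_from_concentration",
    "concentration_from_lambda",
    "lambdas_from_ratio",
    "sample_array",
    "true_label",
    "label_array",
    "expected_type_proportions",
    "poisson_gof",
    "poisson_ks",
    "read_occupancy_csv",
    "read_typed_csv",
]

#: µm^3 per nL (1 nL = 1e-9 L = 1e12 µm^3 / 1e3 ... 1 µm^3 = 1e-15 L = 1e-6 nL)
_UM3_PER_NL = 1.0e6
#: nL per mL
_NL_PER_ML = 1.0e6


@dataclass(frozen=True)
class ChipGeometry:
    """Electrode geometry of the digital-microfluidics chip.

    Parameters
    ----------
    electrode_pitch_um : float
        Electrode width (and droplet footprint side) in micrometers.
    gap_height_um : float
        Spacing between the two chip plates in micrometers.
    array_rows, array_cols : int
        Shape of the single-droplet array produced by one-to-two splitting.
        The default 8 x 8 array holds 64 droplets.
    """

    electrode_pitch_um: float = 250.0
    gap_height_um: float = 50.0
    array_rows: int = 8
    array_cols: int = 8

    def __post_init__(self) -> None:
        if self.electrode_pitch_um <= 0 or self.gap_height_um <= 0:
            raise ValueError("chip dimensions must be positive")
        if self.array_rows < 1 or self.array_cols < 1:
            raise ValueError("array shape must be at least 1 x 1")

    @property
    def n_droplets(self) -> int:
        return self.array_rows * self.array_cols


def droplet_volume(geometry: ChipGeometry) -> float:
    """Volume of a single array droplet in nL.

    The droplet sits on one electrode, so its volume is
    ``pitch^2 x gap_height``.  For the default 250 µm pitch and 50 µm gap
    this is 3.125 nL, i.e. the 64-droplet array totals 0.2 µL.
    """
    g = geometry
    return g.electrode_pitch_um**2 * g.gap_height_um / _UM3_PER_NL


def lambda_from_concentration(concentration_per_ml: float, volume_nl: float) -> float:
    """Mean objects per droplet for a suspension at ``concentration_per_ml``.

    ``lambda = C x V``; e.g. 3.2e5 cells/mL in 3.125 nL droplets gives
    lambda = 1 (one cell per droplet on average, 64 cells in the array).
    """
    if concentration_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    if volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    return concentration_per_ml * volume_nl / _NL_PER_ML


def concentration_from_lambda(lam: float, volume_nl: float) -> float:
    """Inverse of :func:`lambda_from_concentration` (cells per mL)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    return lam * _NL_PER_ML / volume_nl


def lambdas_from_ratio(lambda_target: float, ratio: float) -> tuple[float, float]:
    """Occupancy means of both species from a target:background ratio.

    ``ratio`` is the target:background concentration ratio rho, so the
    background mean is ``lambda_target / rho``.  A 1:1 mixture at
    lambda_target = 1 gives independent Poisson(1) counts for both species.
    """
    if lambda_target <= 0:
        raise ValueError("lambda_target must be positive")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return lambda_target, lambda_target / ratio


@dataclass(frozen=True)
class LoadingSpec:
    """Occupancy means of the two species loaded on the array."""

    lambda_target: float
    lambda_background: float

    def __post_init__(self) -> None:
        if self.lambda_target < 0 or self.lambda_background < 0:
            raise ValueError("occupancy means must be non-negative")

    @classmethod
    def from_ratio(cls, lambda_target: float, ratio: float) -> "LoadingSpec":
        return cls(*lambdas_from_ratio(lambda_target, ratio))

    @classmethod
    def from_concentrations(
        cls,
        target_per_ml: float,
        background_per_ml: float,
        volume_nl: float,
    ) -> "LoadingSpec":
        return cls(
            lambda_from_concentration(target_per_ml, volume_nl),
            lambda_from_concentration(background_per_ml, volume_nl),
        )

    @property
    def ratio(self) -> float:
        """Target:background ratio (inf when no background is loaded)."""
        if self.lambda_background == 0:
            return float("inf")
        return self.lambda_target / self.lambda_background


class DropletLabel(enum.Enum):
    """Content type of a droplet (exhaustive and mutually exclusive)."""

    EMPTY = "empty"
    TARGET_ONLY = "target_only"
    BACKGROUND_ONLY = "background_only"
    MIXED = "mixed"


@dataclass(frozen=True)
class DropletContents:
    """True object counts inside a single droplet."""

    n_target: int
    n_background: int

    def __post_init__(self) -> None:
        if self.n_target < 0 or self.n_background < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class DropletArray:
    """Per-droplet integer counts of target and background objects."""

    n_target: np.ndarray
    n_background: np.ndarray

    def __post_init__(self) -> None:
        self.n_target = np.asarray(self.n_target, dtype=np.int64)
        self.n_background = np.asarray(self.n_background, dtype=np.int64)
        if self.n_target.shape != self.n_background.shape:
            raise ValueError("species count arrays must have the same shape")
        if (self.n_target < 0).any() or (self.n_background < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.n_target.size

    def __getitem__(self, i: int) -> DropletContents:
        return DropletContents(int(self.n_target[i]), int(self.n_background[i]))

    @property
    def total_target(self) -> int:
        return int(self.n_target.sum())

    @property
    def total_background(self) -> int:
        return int(self.n_background.sum())


def sample_array(
    spec: LoadingSpec, n_droplets: int, rng: np.random.Generator
) -> DropletArray:
    """Draw an i.i.d. Poisson droplet array for the two species."""
    if n_droplets < 1:
        raise ValueError("need at least one droplet")
    return DropletArray(
        rng.poisson(spec.lambda_target, n_droplets),
        rng.poisson(spec.lambda_background, n_droplets),
    )


def true_label(d: DropletContents) -> DropletLabel:
    """Type a droplet by its true contents."""
    return _label_from_counts(d.n_target, d.n_background)


def _label_from_counts(n_target: int, n_background: int) -> DropletLabel:
    if n_target == 0 and n_background == 0:
        return DropletLabel.EMPTY
    if n_background == 0:
        return DropletLabel.TARGET_ONLY
    if n_target == 0:
        return DropletLabel.BACKGROUND_ONLY
    return DropletLabel.MIXED


def label_array(array: DropletArray) -> list[DropletLabel]:
    """Vectorised :func:`true_label` over a droplet array."""
    return [
        _label_from_counts(int(t), int(b))
        for t, b in zip(array.n_target, array.n_background)
    ]


def expected_type_proportions(
    lambda_target: float, lambda_background: float
) -> tuple[float, float, float, float]:
    """Closed-form probabilities of the four droplet types.

    With independent Poisson counts, ``P(no target) = exp(-lambda_T)`` and
    ``P(no background) = exp(-lambda_B)``, so::

        p_empty           = exp(-(lambda_T + lambda_B))
        p_target_only     = (1 - exp(-lambda_T)) exp(-lambda_B)
        p_background_only = exp(-lambda_T) (1 - exp(-lambda_B))
        p_mixed           = (1 - exp(-lambda_T)) (1 - exp(-lambda_B))

    The four terms sum to one.  ``p_mixed`` grows with either occupancy
    mean, which is why dense samples need more sorting cycles.
    """
    if lambda_target < 0 or lambda_background < 0:
        raise ValueError("occupancy means must be non-negative")
    qt = np.exp(-lambda_target)  # P(no target)
    qb = np.exp(-lambda_background)
    return (
        float(qt * qb),
        float((1 - qt) * qb),
        float(qt * (1 - qb)),
        float((1 - qt) * (1 - qb)),
    )


@dataclass(frozen=True)
class GofResult:
    """Result of a Poisson goodness-of-fit test on occupancy counts."""

    lambda_hat: float
    statistic: float
    dof: int
    p_value: float
    bin_edges: tuple[int, ...] = field(default=(), repr=False)


class DegenerateDataError(ValueError):
    """Raised when occupancy data cannot support a goodness-of-fit test."""


def poisson_gof(occupancy_counts: np.ndarray) -> GofResult:
    """Chi-square test of Poisson occupancy against its MLE fit.

    The Poisson mean is estimated as the sample mean (its MLE).  Observed
    occupancies are binned at 0, 1, 2, ... with the upper tail pooled so
    every expected bin count is at least 5, and the statistic is compared
    to a chi-square distribution with ``#bins - 2`` degrees of freedom
    (one lost to normalisation, one to the estimated mean).

    Raises
    ------
    DegenerateDataError
        For fewer than two droplets, an all-zero sample, or a sample whose
        fitted distribution leaves fewer than three usable bins.
    """
    counts = np.asarray(occupancy_counts, dtype=np.int64)
    if counts.ndim != 1 or counts.size < 2:
        raise DegenerateDataError("need a flat sample of at least two droplets")
    if (counts < 0).any():
        raise ValueError("occupancy counts must be non-negative")
    n = counts.size
    lam_hat = float(counts.mean())
    if lam_hat == 0:
        raise DegenerateDataError("all droplets empty; Poisson mean estimate is 0")

    dist = stats.poisson(lam_hat)
    # pool the right tail so the last (open) bin has expected count >= 5:
    # tail bin starts at the largest k with n * P(X >= k) >= 5
    tail_start = 1
    while n * dist.sf(tail_start - 0.5) >= 5 and tail_start <= counts.max() + 1:
        tail_start += 1
    tail_start -= 1
    if tail_start < 2:
        raise DegenerateDataError("too few droplets for a binned chi-square test")

    expected = np.empty(tail_start + 1)
    observed = np.empty(tail_start + 1)
    ks = np.arange(tail_start)
    expected[:-1] = n * dist.pmf(ks)
    expected[-1] = n * dist.sf(tail_start - 0.5)
    observed[:-1] = np.bincount(counts, minlength=tail_start)[:tail_start]
    observed[-1] = (counts >= tail_start).sum()

    dof = len(expected) - 2
    statistic = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, dof))
    return GofResult(lam_hat, statistic, dof, p_value, tuple(range(tail_start + 1)))


def poisson_ks(occupancy_counts: np.ndarray) -> GofResult:
    """Kolmogorov-Smirnov variant of :func:`poisson_gof` (secondary check).

    The statistic is the sup-distance between the empirical CDF and the
    fitted Poisson CDF evaluated on the integer support (the continuous
    left-limit correction does not apply to discrete data).  Its p-value
    uses the Kolmogorov distribution, which is conservative both for
    discrete data and for an estimated mean — a companion diagnostic, not
    the primary test.
    """
    counts = np.asarray(occupancy_counts, dtype=np.int64)
    if counts.ndim != 1 or counts.size < 2:
        raise DegenerateDataError("need a flat sample of at least two droplets")
    lam_hat = float(counts.mean())
    if lam_hat == 0:
        raise DegenerateDataError("all droplets empty; Poisson mean estimate is 0")
    n = counts.size
    support = np.arange(counts.max() + 1)
    fitted_cdf = stats.poisson(lam_hat).cdf(support)
    empirical_cdf = np.searchsorted(np.sort(counts), support, side="right") / n
    statistic = float(np.abs(empirical_cdf - fitted_cdf).max())
    p_value = float(stats.kstwo.sf(statistic, n))
    return GofResult(lam_hat, statistic, 0, p_value)


def read_occupancy_csv(path) -> np.ndarray:
    """Read per-droplet object counts (columns droplet_id, n_objects)."""
    df = pd.read_csv(path)
    missing = {"droplet_id", "n_objects"} - set(df.columns)
    if missing:
        raise ValueError(f"occupancy CSV missing columns: {sorted(missing)}")
    return df["n_objects"].to_numpy(dtype=np.int64)


def read_typed_csv(path) -> DropletArray:
    """Read a typed array (columns droplet_id, n_target, n_background)."""
    df = pd.read_csv(path)
    missing = {"droplet_id", "n_target", "n_background"} - set(df.columns)
    if missing:
        raise ValueError(f"typed-array CSV missing columns: {sorted(missing)}")
    return DropletArray(
        df["n_target"].to_numpy(dtype=np.int64),
        df["n_background"].to_numpy(dtype=np.int64),
    )
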