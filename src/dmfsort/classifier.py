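"""Stochastic stand-in for the image-based object detector.

The real system reads every object in a droplet image and assigns it a
class; a detector with precision ``p`` misreads an object's class with
probability ``1 - p``.  The virtual classifier reproduces exactly that
error model: every object is detected (recall is 1), each object
independently keeps its true class with probability ``p`` and flips to the
other class otherwise, and the droplet-level predicted label is derived
from the predicted counts with the same rule used for true labels.  A
mixed droplet is therefore predicted target-only — and wrongly collected —
only when every one of its background objects is misread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loading import DropletArray, DropletContents, DropletLabel, _label_from_counts

__all__ = ["ClassifierSpec", "DetectionOutcome", "detect_droplet", "detect_array",
           "collection_probability"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Per-object read precision of the (virtual) detector.

    ``precision`` is the probability that a target object is read as a
    target; ``precision_background`` the same for background objects.  The
    detector the simulator emulates has a single symmetric precision, so
    the background value defaults to ``precision``.
    """

    precision: float
    precision_background: float | None = None

    def __post_init__(self) -> None:
        for p in (self.precision, self.precision_background):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("precision must lie in [0, 1]")

    @property
    def p_target(self) -> float:
        return self.precision

    @property
    def p_background(self) -> float:
        if self.precision_background is None:
            return self.precision
        return self.precision_background


@dataclass(frozen=True)
class DetectionOutcome:
    """Predicted per-class counts and droplet label for one droplet."""

    predicted_target: int
    predicted_background: int
    predicted_label: DropletLabel


def detect_droplet(
    d: DropletContents, spec: ClassifierSpec, rng: np.random.Generator
) -> DetectionOutcome:
    """Read one droplet through the noisy per-object channel."""
    read_as_target = rng.binomial(d.n_target, spec.p_target) + rng.binomial(
        d.n_background, 1.0 - spec.p_background
    )
    total = d.n_target + d.n_background
    return DetectionOutcome(
        int(read_as_target),
        int(total - read_as_target),
        _label_from_counts(int(read_as_target), int(total - read_as_target)),
    )


def detect_array(
    array: DropletArray, spec: ClassifierSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[DropletLabel]]:
    """Vectorised :func:`detect_droplet` over a droplet array."""
    read_as_target = rng.binomial(array.n_target, spec.p_target) + rng.binomial(
        array.n_background, 1.0 - spec.p_background
    )
    total = array.n_target + array.n_background
    predicted_background = total - read_as_target
    labels = [
        _label_from_counts(int(t), int(b))
        for t, b in zip(read_as_target, predicted_background)
    ]
    return read_as_target, predicted_background, labels


def collection_probability(d: DropletContents, precision: float,
                           precision_background: float | None = None) -> float:
    """Probability that a droplet is predicted target-only (hence collected).

    A droplet is predicted target-only iff every object in it is read as a
    target, which requires all targets read correctly and all background
    objects misread: ``p_T^h (1 - p_B)^b`` for ``h + b >= 1``, and 0 for an
    empty droplet (no objects means a predicted empty label).
    """
    if not 0.0 <= precision <= 1.0:
        raise ValueError("precision must lie in [0, 1]")
    p_b = precision if precision_background is None else precision_background
    if d.n_target + d.n_background == 0:
        return 0.0
    return precision**d.n_target * (1.0 - p_b) ** d.n_background
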