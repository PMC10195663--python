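"""Fuzzy-set primitives on the priority universe X = [0, 100].

Three membership shapes cover every variable of the index: singletons for
categorical inputs (a category is mapped onto a fixed location on the
universe), trapezoids for continuous inputs, and Gaussians for the final
prioritizing-index output classes.  Crisp labels are assigned by maximum
membership grade; the final 0-100 priority value comes from centroid
defuzzification of the activated output sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "Shape",
    "Priority",
    "UniverseSpec",
    "MembershipFunction",
    "LabeledFuzzySet",
    "FuzzyAssignment",
    "UNDETERMINED",
    "eval_membership",
    "fuzzify",
    "centroid_defuzzify",
]

#: label returned when a value activates no fuzzy set at all
UNDETERMINED = "undetermined"


class Shape(str, Enum):
    SINGLETON = "singleton"
    TRAPEZOID = "trapezoid"
    GAUSSIAN = "gaussian"


class Priority(str, Enum):
    """Priority annotation of a labelled set, used only to break grade ties.

    Ordering (for tie-breaks): high > middle > low > undetermined.
    """

    HIGH = "high"
    MIDDLE = "middle"
    LOW = "low"
    UNDETERMINED = "undetermined"

    @property
    def rank(self) -> int:
        return {"undetermined": 0, "low": 1, "middle": 2, "high": 3}[self.value]


@dataclass(frozen=True)
class UniverseSpec:
    """Discretisation of the data universe for numeric defuzzification."""

    lower: float = 0.0
    upper: float = 100.0
    resolution: float = 0.01

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("universe requires lower < upper")
        if not self.resolution > 0:
            raise ValueError("universe resolution must be positive")


@dataclass(frozen=True)
class MembershipFunction:
    """One membership shape with its parameters.

    Trapezoid: bottom-left ``a``, top-left ``m``, top-right ``n``,
    bottom-right ``b`` (a <= m <= n <= b; degenerate ramps where a == m or
    n == b behave as steps).  Gaussian: centre ``mu``, width ``sigma``.
    Singleton: location ``a``; values within ``sd_singleton`` of ``a`` get
    grade 1, everything else 0 (the indicator reading of a Gaussian of
    vanishing width).
    """

    shape: Shape
    a: float = 0.0
    m: float = 0.0
    n: float = 0.0
    b: float = 0.0
    mu: float = 0.0
    sigma: float = 1.0
    sd_singleton: float = 0.001

    def __post_init__(self) -> None:
        if self.shape is Shape.TRAPEZOID:
            if not (self.a <= self.m <= self.n <= self.b):
                raise ValueError(
                    f"trapezoid requires a <= m <= n <= b, got "
                    f"({self.a}, {self.m}, {self.n}, {self.b})"
                )
        elif self.shape is Shape.GAUSSIAN:
            if not self.sigma > 0:
                raise ValueError("gaussian requires sigma > 0")
        elif self.shape is Shape.SINGLETON:
            if not self.sd_singleton > 0:
                raise ValueError("singleton tolerance must be positive")

    @property
    def support(self) -> tuple[float, float]:
        """Interval outside which the grade is (numerically) zero."""
        if self.shape is Shape.TRAPEZOID:
            return (self.a, self.b)
        if self.shape is Shape.SINGLETON:
            return (self.a - self.sd_singleton, self.a + self.sd_singleton)
        # exp(-8.5^2/2) ~ 2e-16: below double precision of the peak
        return (self.mu - 8.5 * self.sigma, self.mu + 8.5 * self.sigma)


def eval_membership(x: float, f: MembershipFunction) -> float:
    """Membership grade of crisp value ``x`` in ``f``; always in [0, 1]."""
    if not math.isfinite(x):
        raise ValueError(f"membership undefined for non-finite value {x!r}")
    if f.shape is Shape.SINGLETON:
        return 1.0 if abs(x - f.a) <= f.sd_singleton else 0.0
    if f.shape is Shape.GAUSSIAN:
        z = (x - f.mu) / f.sigma
        return math.exp(-0.5 * z * z)
    # trapezoid
    if x < f.a or x > f.b:
        return 0.0
    if f.m <= x <= f.n:
        return 1.0
    if x < f.m:  # rising ramp; a == m handled above (x < a or x >= m)
        return (x - f.a) / (f.m - f.a)
    return (f.b - x) / (f.b - f.n)


def _eval_grid(x: np.ndarray, f: MembershipFunction) -> np.ndarray:
    """Vectorised eval_membership over a grid (same semantics)."""
    if f.shape is Shape.SINGLETON:
        return (np.abs(x - f.a) <= f.sd_singleton).astype(float)
    if f.shape is Shape.GAUSSIAN:
        z = (x - f.mu) / f.sigma
        return np.exp(-0.5 * z * z)
    out = np.zeros_like(x)
    out[(x >= f.m) & (x <= f.n)] = 1.0
    if f.m > f.a:
        rise = (x >= f.a) & (x < f.m)
        out[rise] = (x[rise] - f.a) / (f.m - f.a)
    if f.b > f.n:
        fall = (x > f.n) & (x <= f.b)
        out[fall] = (f.b - x[fall]) / (f.b - f.n)
    return out


@dataclass(frozen=True)
class LabeledFuzzySet:
    label: str
    function: MembershipFunction
    priority: Priority = Priority.UNDETERMINED


@dataclass
class FuzzyAssignment:
    """Crisp label chosen by maximum grade, with the full grade vector."""

    label: str
    grade: float
    all_grades: dict[str, float] = field(default_factory=dict)


def fuzzify(x: float, sets: list[LabeledFuzzySet]) -> FuzzyAssignment:
    """Assign ``x`` the label of maximal membership grade.

    Ties are broken toward the set with the higher priority annotation
    (conservative: a borderline value is flagged at the more attention-worthy
    label).  If every grade is zero the label is ``"undetermined"`` at
    grade 0.
    """
    if not sets:
        raise ValueError("fuzzify requires at least one labelled set")
    grades = {s.label: eval_membership(x, s.function) for s in sets}
    best = max(sets, key=lambda s: (grades[s.label], s.priority.rank))
    if grades[best.label] <= 0.0:
        return FuzzyAssignment(UNDETERMINED, 0.0, grades)
    return FuzzyAssignment(best.label, grades[best.label], grades)


def centroid_defuzzify(
    activations: Mapping[str, tuple[float, MembershipFunction]],
    universe: UniverseSpec | None = None,
) -> float:
    """Centroid of the max-min aggregate of the activated output sets.

    Each activation clips its membership function at the activation grade
    (min); the clipped sets are combined pointwise by max; the crisp result is
    the centre of mass of the aggregate.  The integration grid covers the
    whole support of every activated set even where it spills past the
    universe bounds, so a symmetric set's centroid is its centre exactly
    (Gaussian tails are not cut off at 100).
    """
    universe = universe or UniverseSpec()
    active = [(g, f) for g, f in activations.values() if g > 0.0]
    if not active:
        raise ValueError("no activated output class: all grades are zero")
    lo = min(universe.lower, *(f.support[0] for _, f in active))
    hi = max(universe.upper, *(f.support[1] for _, f in active))
    npts = int(math.ceil((hi - lo) / universe.resolution)) + 1
    x = np.linspace(lo, hi, npts)
    agg = np.zeros_like(x)
    for grade, f in active:
        np.maximum(agg, np.minimum(_eval_grid(x, f), grade), out=agg)
    mass = np.trapezoid(agg, x)
    if mass <= 0.0:
        raise ValueError("activated aggregate has zero area")
    return float(np.trapezoid(x * agg, x) / mass)
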