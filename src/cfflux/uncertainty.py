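"""Arithmetic and resampling for quantities with multiplicative (lognormal) uncertainty.

Every estimate in the pipeline is carried as a :class:`LognormalQuantity`: a
median together with a multiplication error factor ``f >= 1``.  The implied
distribution is lognormal with shape parameter ``s = ln(f)``, so an ``f = 2``
means a 68% (one-sigma) probability that the true value lies between half and
double the median.

Products and ratios of independent lognormals stay lognormal and close under
the root-sum-square rule on the log-shapes,

    f_xy = exp( sqrt( ln(f_x)^2 + ln(f_y)^2 ) ).

Sums do not, so :func:`bootstrap_sum` propagates them by Monte-Carlo
resampling followed by a lognormal refit; :func:`apply_uniform_factor` does
the same for a multiplicative correction whose value is only known to lie
uniformly within a range.  All stochastic operations take an explicit seed
and are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LognormalQuantity",
    "make_lognormal",
    "from_interval",
    "multiply",
    "divide",
    "bootstrap_sum",
    "apply_uniform_factor",
    "fit_lognormal",
    "ci95",
]

#: z-score bounding the central 95% of a standard normal.
Z95 = 1.959963984540054


@dataclass(frozen=True)
class LognormalQuantity:
    """A positive quantity with multiplicative uncertainty.

    Parameters
    ----------
    median
        Median of the implied lognormal distribution (units carried by
        context).
    factor
        Multiplication error factor ``f >= 1``; the 68% central interval is
        ``[median / factor, median * factor]``.  ``factor == 1`` denotes an
        exact value.
    """

    median: float
    factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.median > 0 and math.isfinite(self.median)):
            raise ValueError(f"median must be positive and finite, got {self.median}")
        if not (self.factor >= 1 and math.isfinite(self.factor)):
            raise ValueError(f"error factor must be >= 1, got {self.factor}")

    @property
    def s(self) -> float:
        """Lognormal shape parameter, ``ln(factor)``."""
        return math.log(self.factor)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` variates from the implied lognormal distribution."""
        return rng.lognormal(mean=math.log(self.median), sigma=self.s, size=n)

    def scaled(self, k: float) -> "LognormalQuantity":
        """Multiply the median by an exact positive scalar ``k``."""
        return LognormalQuantity(self.median * k, self.factor)

    def __mul__(self, other: "LognormalQuantity | float") -> "LognormalQuantity":
        if isinstance(other, LognormalQuantity):
            return multiply(self, other)
        return self.scaled(float(other))

    __rmul__ = __mul__

    def __truediv__(self, other: "LognormalQuantity | float") -> "LognormalQuantity":
        if isinstance(other, LognormalQuantity):
            return divide(self, other)
        return self.scaled(1.0 / float(other))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LognormalQuantity(median={self.median:.6g}, factor={self.factor:.4g})"


def make_lognormal(median: float, factor: float = 1.0) -> LognormalQuantity:
    """Construct a :class:`LognormalQuantity` from a median and error factor."""
    return LognormalQuantity(float(median), float(factor))


def from_interval(median: float, ci_low: float, ci_high: float) -> LognormalQuantity:
    """Convert a 95% confidence interval into a multiplication error factor.

    The interval width is mapped onto the lognormal shape via
    ``s = ln(ci_high / ci_low) / (2 * 1.96)``; asymmetric intervals are
    symmetrized on the log scale and the stated median is kept.
    """
    if not (0 < ci_low <= median <= ci_high):
        raise ValueError(
            f"interval must satisfy 0 < low <= median <= high, "
            f"got ({ci_low}, {median}, {ci_high})"
        )
    s = math.log(ci_high / ci_low) / (2 * Z95)
    return LognormalQuantity(float(median), math.exp(s))


def multiply(x: LognormalQuantity, y: LognormalQuantity) -> LognormalQuantity:
    """Product of two independent lognormal quantities (exact, no sampling)."""
    s = math.hypot(x.s, y.s)
    return LognormalQuantity(x.median * y.median, math.exp(s))


def divide(x: LognormalQuantity, y: LognormalQuantity) -> LognormalQuantity:
    """Ratio ``x / y`` of independent lognormal quantities.

    The reciprocal of a lognormal is lognormal with the same shape, so the
    factor equals that of ``multiply(x, y)``.  The operands are treated as
    independent: ``divide(x, x)`` has median 1 but a nontrivial factor.
    """
    s = math.hypot(x.s, y.s)
    return LognormalQuantity(x.median / y.median, math.exp(s))


def fit_lognormal(samples: Sequence[float] | np.ndarray) -> LognormalQuantity:
    """Fit a lognormal to positive samples on the log scale.

    median = exp(mean(ln x)), factor = exp(sd(ln x)).  With this estimator the
    fit exactly inverts sampling from a :class:`LognormalQuantity` in the
    large-n limit, and it is robust to the heavy right tail.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to fit a lognormal")
    if not np.all(arr > 0):
        raise ValueError("all samples must be positive")
    logs = np.log(arr)
    return LognormalQuantity(float(np.exp(logs.mean())), float(np.exp(logs.std())))


def bootstrap_sum(
    quantities: Iterable[LognormalQuantity],
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> LognormalQuantity:
    """Propagate uncertainty through a sum by resampling.

    Sums of lognormals have no closed form, so ``n_samples`` joint draws are
    taken (independently per summand), summed per draw, and a lognormal is
    refitted to the sums.
    """
    qs = list(quantities)
    if not qs:
        raise ValueError("bootstrap_sum requires a non-empty list of quantities")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = _as_rng(seed)
    draws = np.stack([q.sample(rng, n_samples) for q in qs])
    return fit_lognormal(draws.sum(axis=0))


def apply_uniform_factor(
    x: LognormalQuantity,
    low: float = 1.0,
    high: float = 2.0,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> LognormalQuantity:
    """Fold a uniformly distributed multiplicative correction into ``x``.

    Each of ``n_iter`` iterations multiplies a draw of ``x`` by an adjustment
    factor drawn uniformly in ``[low, high]``; a lognormal is then fitted to
    the products.  A degenerate range (``low == high``) is applied exactly.
    """
    if low < 0:
        raise ValueError(f"adjustment range must be non-negative, got low={low}")
    if low > high:
        raise ValueError(f"adjustment range inverted: [{low}, {high}]")
    if low == high:
        return x.scaled(low)
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = _as_rng(seed)
    products = x.sample(rng, n_iter) * rng.uniform(low, high, n_iter)
    return fit_lognormal(products)


def ci95(x: LognormalQuantity) -> tuple[float, float]:
    """Central 95% interval ``[median * exp(-1.96 s), median * exp(+1.96 s)]``."""
    half = math.exp(Z95 * x.s)
    return (x.median / half, x.median * half)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
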