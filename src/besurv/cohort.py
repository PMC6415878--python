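"""Annual cohort projection and discounting.

The population attending surveillance endoscopy grows geometrically from the
year-1 count (default +20%/year over 7 years). Exact (fractional) expected
values are carried internally; integers are produced only at report time by
half-up rounding, which reproduces both the printed yearly populations and
the printed cumulative total.

Money after year 1 is discounted at an annual rate (default 3.5%); year 1 is
undiscounted. Event counts (biopsies, adverse events, eradications) are
reported undiscounted — only money is discounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CohortTrace",
    "project_population",
    "discount_factors",
    "cumulative_population",
    "build_trace",
    "round_half_up",
]


def round_half_up(x: float | np.ndarray) -> np.ndarray | int:
    """Round half away from zero (the convention of the printed tables)."""
    if np.isscalar(x):
        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
    arr = np.asarray(x, dtype=float)
    return np.where(arr >= 0, np.floor(arr + 0.5), -np.floor(-arr + 0.5)).astype(np.int64)


def project_population(
    n1: float, growth: float, years: int, *, rounding: str = "exact"
) -> np.ndarray:
    """Yearly populations attending endoscopy.

    Parameters
    ----------
    n1 : year-1 population (> 0).
    growth : annual growth fraction (>= 0).
    years : horizon length in years (>= 1).
    rounding : ``"exact"`` carries the geometric sequence in full precision
        (default; integers appear only at report time); ``"yearly"`` rounds
        each year to an integer before applying the next growth step.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if n1 <= 0:
        raise ValueError(f"n1 must be > 0, got {n1}")
    if growth < 0:
        raise ValueError(f"growth must be >= 0, got {growth}")
    if rounding == "exact":
        return n1 * (1.0 + growth) ** np.arange(years)
    if rounding == "yearly":
        pops = np.empty(years)
        pops[0] = round_half_up(n1)
        for t in range(1, years):
            pops[t] = round_half_up(pops[t - 1] * (1.0 + growth))
        return pops
    raise ValueError(f"rounding must be 'exact' or 'yearly', got {rounding!r}")


def discount_factors(rate: float, years: int) -> np.ndarray:
    """Per-year discount factors (1 + rate)^-(t-1); year 1 is undiscounted."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    return (1.0 + rate) ** -np.arange(years, dtype=float)


@dataclass(frozen=True)
class CohortTrace:
    """Per-year population counts and discount factors over the horizon."""

    populations: np.ndarray  # exact expected values, length T
    factors: np.ndarray  # discount factors, length T

    def __post_init__(self) -> None:
        if len(self.populations) != len(self.factors):
            raise ValueError("populations and factors must have equal length")

    @property
    def years(self) -> int:
        return len(self.populations)

    @property
    def populations_rounded(self) -> np.ndarray:
        return round_half_up(self.populations)

    @property
    def cumulative(self) -> float:
        return float(self.populations.sum())

    @property
    def cumulative_rounded(self) -> int:
        return int(round_half_up(self.cumulative))

    @property
    def discounted_cumulative(self) -> float:
        return float((self.populations * self.factors).sum())


def cumulative_population(trace: CohortTrace) -> int:
    """Total population over the horizon, rounded at report time."""
    return trace.cumulative_rounded


def build_trace(n1: float, growth: float, years: int, discount_rate: float) -> CohortTrace:
    return CohortTrace(
        populations=project_population(n1, growth, years),
        factors=discount_factors(discount_rate, years),
    )
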