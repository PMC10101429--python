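"""Age-specific rates, direct standardization and moving-average smoothing.

Direct standardization weights the age-specific rates of a study population
by the age distribution of a fixed external standard, so that rates from
populations with different age structures become comparable. The bundled
standard is the WHO world standard population; when a Lexis grid truncates
the age range (e.g. 10-14 ... 80+), the standard's weights are collapsed to
the grid's groups and renormalized to sum to one over that range.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .grid import LexisGrid, LexisTable, ValidationError

PER = 100_000.0


@dataclass
class StandardPopulation:
    """Age-group weights (proportions summing to 1) of a standard population."""

    age_lower_bounds: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.age_lower_bounds = np.asarray(self.age_lower_bounds, float)
        self.weights = np.asarray(self.weights, float)
        if self.age_lower_bounds.shape != self.weights.shape:
            raise ValidationError("age bounds and weights must have equal length")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights must be finite and >= 0")
        total = self.weights.sum()
        if total <= 0:
            raise ValidationError("weights must not all be zero")
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total

    def aligned_to(self, grid: LexisGrid) -> "StandardPopulation":
        """Collapse to the grid's age groups (open top interval absorbs the
        tail) and renormalize. Alignment is strict below the open interval:
        every grid bound must exist in the standard."""
        w = np.zeros(grid.n_ages)
        bounds = list(self.age_lower_bounds)
        for i, lo in enumerate(grid.age_lower_bounds):
            if lo not in bounds:
                raise ValidationError(f"standard population has no age group starting at {lo}")
            if grid.open_age and i == grid.n_ages - 1:
                w[i] = self.weights[self.age_lower_bounds >= lo].sum()
            else:
                j = bounds.index(lo)
                w[i] = self.weights[j]
        return StandardPopulation(np.asarray(grid.age_lower_bounds, float), w)


def who_world_standard() -> StandardPopulation:
    """The WHO world standard population (5-year groups, 0 to 100+)."""
    with resources.files("lexisapc.data").joinpath("who_world_standard.csv").open() as fh:
        df = pd.read_csv(fh)
    return StandardPopulation(df["age_low"].to_numpy(), df["weight"].to_numpy())


def age_specific_rates(table: LexisTable, per: float = PER) -> np.ndarray:
    """I x J table of rates per `per` (default 100,000) person-years."""
    return per * table.deaths / table.person_years


def direct_standardize(age_rates: np.ndarray, std: StandardPopulation) -> float | np.ndarray:
    """Directly standardized rate: sum of weight_a * rate_a over age groups.

    `age_rates` may be a length-I vector (one period) or an I x J matrix, in
    which case one standardized rate per period (column) is returned.
    """
    r = np.asarray(age_rates, float)
    if r.shape[0] != std.weights.shape[0]:
        raise ValidationError(
            f"{r.shape[0]} age-specific rates do not align with "
            f"{std.weights.shape[0]} standard-population groups"
        )
    out = std.weights @ r
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class RateSeries:
    """An ordered series of rates per 100,000 person-years."""

    labels: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, float)
        self.values = np.asarray(self.values, float)
        if self.labels.shape != self.values.shape or self.labels.ndim != 1:
            raise ValidationError("labels and values must be 1-D of equal length")
        if np.any(np.diff(self.labels) <= 0):
            raise ValidationError("labels must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("rates must be >= 0")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.labels, name="rate_per_100000")


def standardized_series(table: LexisTable, std: StandardPopulation) -> RateSeries:
    """One directly standardized rate per period of a Lexis table."""
    rates = age_specific_rates(table)
    vals = direct_standardize(rates, std.aligned_to(table.grid))
    return RateSeries(table.grid.period_midpoints, vals)


def moving_average(series: RateSeries, window: int = 3) -> RateSeries:
    """Centered moving average; the series is shortened by (window-1)/2 at
    each end rather than padded (padding would fabricate data)."""
    if window % 2 == 0 or window < 1:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    n = series.values.size
    if n < window:
        raise ValidationError(f"series of length {n} is shorter than window {window}")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(series.values, kernel, mode="valid")
    half = (window - 1) // 2
    labels = series.labels[half: n - half]
    return RateSeries(labels, smoothed)
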