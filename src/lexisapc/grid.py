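"""Lexis grids and Lexis tables.

A Lexis table cross-classifies death counts and person-years by age group
(rows) and calendar period (columns); birth cohorts run along its diagonals.
The default grid matches a common registry layout: fifteen 5-year age groups
from 10-14 up to the open interval 80+, and eight 5-year periods from 1980-84
to 2015-19, giving I + J - 1 = 22 birth cohorts with midpoints 1900 ... 2005.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ValidationError(ValueError):
    """Raised when inputs violate a structural contract."""


# midpoint offset for the open age interval (80+): treated as if it were a
# regular 5-year group, i.e. 80 + 2.5
_HALF = 0.5


@dataclass(frozen=True)
class LexisGrid:
    """Age-group x calendar-period grid.

    Parameters
    ----------
    age_lower_bounds
        Lower bound of each age group in years, strictly increasing and
        equally spaced by ``age_width``.
    period_lower_bounds
        Lower bound (calendar year) of each period, strictly increasing and
        equally spaced by ``period_width``.
    age_width, period_width
        Interval widths in years; both default to 5.
    open_age
        Whether the last age interval is open-ended (e.g. 80+). The open
        interval is assigned the symmetric midpoint ``lower + width/2``.
    """

    age_lower_bounds: tuple = tuple(range(10, 85, 5))
    period_lower_bounds: tuple = tuple(range(1980, 2020, 5))
    age_width: float = 5.0
    period_width: float = 5.0
    open_age: bool = True

    def __post_init__(self):
        a = np.asarray(self.age_lower_bounds, dtype=float)
        p = np.asarray(self.period_lower_bounds, dtype=float)
        if a.ndim != 1 or a.size < 2 or p.ndim != 1 or p.size < 2:
            raise ValidationError("grid needs at least two age groups and two periods")
        for name, bounds, width in (("age", a, self.age_width), ("period", p, self.period_width)):
            d = np.diff(bounds)
            if not np.all(d > 0):
                raise ValidationError(f"{name} lower bounds must be strictly increasing")
            if not np.allclose(d, width):
                raise ValidationError(f"{name} lower bounds must be equally spaced by {width}")
        object.__setattr__(self, "age_lower_bounds", tuple(a))
        object.__setattr__(self, "period_lower_bounds", tuple(p))

    # --- shape ---------------------------------------------------------
    @property
    def n_ages(self) -> int:
        return len(self.age_lower_bounds)

    @property
    def n_periods(self) -> int:
        return len(self.period_lower_bounds)

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    @property
    def shape(self) -> tuple:
        return (self.n_ages, self.n_periods)

    # --- midpoints -----------------------------------------------------
    @property
    def age_midpoints(self) -> np.ndarray:
        return np.asarray(self.age_lower_bounds) + self.age_width * _HALF

    @property
    def period_midpoints(self) -> np.ndarray:
        return np.asarray(self.period_lower_bounds) + self.period_width * _HALF

    @property
    def cohort_midpoints(self) -> np.ndarray:
        """Midpoints of the I+J-1 diagonal birth cohorts (period - age), ascending."""
        p, a = np.meshgrid(self.period_midpoints, self.age_midpoints)
        return np.unique(np.round(p - a, 6))

    def cohort_midpoint_table(self) -> np.ndarray:
        """I x J table of cohort midpoints c = p - a."""
        p, a = np.meshgrid(self.period_midpoints, self.age_midpoints)
        return p - a

    def cohort_index_table(self) -> np.ndarray:
        """I x J table of 1-based cohort indices k = j - i + I."""
        i = np.arange(1, self.n_ages + 1)[:, None]
        j = np.arange(1, self.n_periods + 1)[None, :]
        return j - i + self.n_ages

    def age_group_label(self, i: int) -> str:
        lo = self.age_lower_bounds[i]
        if self.open_age and i == self.n_ages - 1:
            return f"{lo:g}+"
        return f"{lo:g}-{lo + self.age_width - 1:g}"

    def period_label(self, j: int) -> str:
        lo = self.period_lower_bounds[j]
        return f"{lo:g}-{lo + self.period_width - 1:g}"


def cohort_index(i: int, j: int, n_ages: int) -> int:
    """1-based cohort index k = j - i + I.

    The oldest cohort (i = I, j = 1) gets k = 1; the youngest (i = 1, j = J)
    gets k = I + J - 1.
    """
    if not 1 <= i <= n_ages:
        raise ValidationError(f"age index {i} outside 1..{n_ages}")
    if j < 1:
        raise ValidationError(f"period index {j} must be >= 1")
    return j - i + n_ages


@dataclass
class LexisTable:
    """Deaths and person-years on a Lexis grid for one scenario.

    Death counts are kept as reals: underreporting correction multiplies
    integer registry counts by factors > 1 and the result is fractional.
    """

    grid: LexisGrid
    deaths: np.ndarray
    person_years: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        if self.deaths.shape != self.grid.shape:
            raise ValidationError(
                f"deaths shape {self.deaths.shape} does not match grid {self.grid.shape}"
            )
        if self.person_years.shape != self.grid.shape:
            raise ValidationError(
                f"person_years shape {self.person_years.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.deaths)) or np.any(self.deaths < 0):
            raise ValidationError("deaths must be finite and >= 0")
        if not np.all(np.isfinite(self.person_years)) or np.any(self.person_years <= 0):
            raise ValidationError("person_years must be finite and > 0")

    def with_person_years(self, person_years) -> "LexisTable":
        """Return a copy with exposures replaced (scalar broadcast allowed)."""
        py = np.broadcast_to(np.asarray(person_years, dtype=float), self.grid.shape).copy()
        return LexisTable(self.grid, self.deaths.copy(), py, self.label)

    def with_deaths(self, deaths) -> "LexisTable":
        return LexisTable(self.grid, np.asarray(deaths, dtype=float), self.person_years.copy(), self.label)

    def copy(self, label: str | None = None) -> "LexisTable":
        return LexisTable(
            self.grid, self.deaths.copy(), self.person_years.copy(),
            self.label if label is None else label,
        )
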