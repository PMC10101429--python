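"""Synthetic Lexis tables with known age-period-cohort structure.

The generator mirrors the model that is later fitted: cell deaths are
Poisson with mean N_ij * exp(eta_ij), where the log-rate surface

    eta_ij = baseline + age_curve[i] + drift * (p_j - p_0)
             + period_curvature[j] + cohort_curvature[k(i,j)]

decomposes into an age curve, a single identifiable linear trend (the
drift, per calendar year, anchored at the first period midpoint p_0) and
zero-mean, zero-slope period and cohort curvatures. Supplied curvature
sequences are re-detrended internally (OLS on their midpoints) so the drift
parameter is, by construction, the unique linear trend of the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import LexisGrid, LexisTable, ValidationError


def detrend_sequence(values: np.ndarray, midpoints: np.ndarray) -> np.ndarray:
    """Remove the OLS fit on (1, midpoint) from a sequence.

    The result has mean 0 and slope 0 when regressed on the midpoints, which
    makes curvature inputs canonical: any linear-in-midpoint component is an
    unidentifiable reallocation of drift and baseline, not curvature.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(midpoints, dtype=float)
    if v.shape != m.shape:
        raise ValidationError(f"curvature length {v.shape} does not match midpoints {m.shape}")
    X = np.column_stack([np.ones_like(m), m])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


@dataclass
class APCTruth:
    """Generating parameters of a synthetic log-rate surface.

    Parameters
    ----------
    baseline_log_rate
        log(deaths per person-year) at the first period midpoint for an age
        with zero age-curve offset.
    age_curve
        Log-rate offsets, one per age midpoint.
    drift_per_year
        Additive log-rate change per calendar year: the estimable sum of the
        period and cohort linear trends.
    period_curvature, cohort_curvature
        Nonlinear log-rate offsets per period / cohort midpoint; detrended on
        construction so they carry no mean or linear trend.
    """

    baseline_log_rate: float = 0.0
    age_curve: np.ndarray | None = None
    drift_per_year: float = 0.0
    period_curvature: np.ndarray | None = None
    cohort_curvature: np.ndarray | None = None

    def resolved(self, grid: LexisGrid) -> "APCTruth":
        """Fill missing sequences with zeros and detrend curvatures for `grid`."""
        I, J = grid.shape
        K = grid.n_cohorts
        age = np.zeros(I) if self.age_curve is None else np.asarray(self.age_curve, float)
        per = np.zeros(J) if self.period_curvature is None else np.asarray(self.period_curvature, float)
        coh = np.zeros(K) if self.cohort_curvature is None else np.asarray(self.cohort_curvature, float)
        if age.shape != (I,):
            raise ValidationError(f"age_curve length {age.shape} != I={I}")
        if not (np.all(np.isfinite(age)) and np.all(np.isfinite(per)) and np.all(np.isfinite(coh))
                and np.isfinite(self.baseline_log_rate) and np.isfinite(self.drift_per_year)):
            raise ValidationError("all truth values must be finite")
        per = detrend_sequence(per, grid.period_midpoints)
        coh = detrend_sequence(coh, grid.cohort_midpoints)
        return APCTruth(self.baseline_log_rate, age, self.drift_per_year, per, coh)


@dataclass
class SimConfig:
    """Everything needed to draw one synthetic Lexis table."""

    grid: LexisGrid = field(default_factory=LexisGrid)
    truth: APCTruth = field(default_factory=APCTruth)
    person_years_per_cell: float | np.ndarray = 1e6
    seed: int = 0
    label: str = "synthetic"

    def person_years_table(self) -> np.ndarray:
        py = np.broadcast_to(np.asarray(self.person_years_per_cell, float), self.grid.shape)
        if np.any(py <= 0) or not np.all(np.isfinite(py)):
            raise ValidationError("person_years must be finite and > 0")
        return py.copy()


def linear_predictor(truth: APCTruth, grid: LexisGrid) -> np.ndarray:
    """I x J table of log-rates eta_ij implied by a truth on a grid."""
    t = truth.resolved(grid)
    a = grid.age_midpoints
    p = grid.period_midpoints
    cohorts = grid.cohort_midpoints
    p0 = p[0]
    eta = np.empty(grid.shape)
    # cohort midpoint for cell (i, j) and its index into the sorted cohort list
    ctab = grid.cohort_midpoint_table()
    kidx = np.searchsorted(cohorts, np.round(ctab, 6).ravel()).reshape(grid.shape)
    for i in range(grid.n_ages):
        for j in range(grid.n_periods):
            eta[i, j] = (
                t.baseline_log_rate
                + t.age_curve[i]
                + t.drift_per_year * (p[j] - p0)
                + t.period_curvature[j]
                + t.cohort_curvature[kidx[i, j]]
            )
    return eta


def simulate_lexis(config: SimConfig) -> LexisTable:
    """Draw one Poisson Lexis table; a pure function of (config, seed)."""
    py = config.person_years_table()
    eta = linear_predictor(config.truth, config.grid)
    mu = py * np.exp(eta)
    rng = np.random.default_rng(config.seed)
    deaths = rng.poisson(mu).astype(float)
    return LexisTable(config.grid, deaths, py, label=config.label)


def simulate_replicates(config: SimConfig, n: int):
    """Yield n tables, advancing the seed deterministically (seed + r)."""
    for r in range(n):
        yield simulate_lexis(
            SimConfig(config.grid, config.truth, config.person_years_per_cell,
                      seed=config.seed + r, label=f"{config.label}[{r}]")
        )


def default_truth(grid: LexisGrid | None = None) -> APCTruth:
    """A realistic generating truth for male suicide mortality.

    Baseline around 9 deaths per 100,000 person-years with rates rising
    roughly threefold from adolescence to old age, a gentle upward drift of
    0.8%/year, and mild period and cohort curvature.
    """
    grid = grid or LexisGrid()
    a = grid.age_midpoints
    age_curve = 0.55 * np.log(a / a.mean())  # monotone increase with age
    per = 0.03 * np.sin(2 * np.pi * (grid.period_midpoints - grid.period_midpoints[0]) / 40.0)
    coh = 0.05 * np.cos(2 * np.pi * (grid.cohort_midpoints - grid.cohort_midpoints[0]) / 105.0)
    return APCTruth(
        baseline_log_rate=np.log(9.0 / 1e5),
        age_curve=age_curve,
        drift_per_year=0.008,
        period_curvature=per,
        cohort_curvature=coh,
    )


def toy_fixture() -> LexisTable:
    """Small deterministic 4-age x 3-period table for unit tests and docs."""
    grid = LexisGrid(
        age_lower_bounds=(20, 25, 30, 35),
        period_lower_bounds=(1990, 1995, 2000),
    )
    deaths = np.array([
        [3.0, 4.0, 6.0],
        [5.0, 7.0, 8.0],
        [9.0, 10.0, 12.0],
        [11.0, 13.0, 15.0],
    ])
    person_years = np.array([
        [50_000.0, 52_000.0, 54_000.0],
        [48_000.0, 50_000.0, 52_000.0],
        [46_000.0, 48_000.0, 50_000.0],
        [44_000.0, 46_000.0, 48_000.0],
    ])
    return LexisTable(grid, deaths, person_years, label="toy")
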