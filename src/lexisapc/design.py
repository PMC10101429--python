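"""Design matrices for age-period-cohort Poisson models.

The three time scales of a Lexis table are exactly collinear
(cohort = period - age), so individual age, period and cohort effects are
not identifiable. What is identifiable — and what these designs expose
directly — are estimable functions: the age curve, a single linear trend
(the *drift*, the sum of the period and cohort slopes, per calendar year)
and the *curvatures* (detrended, nonlinear parts) of the period and cohort
effects.

Construction:

* smooth effects use natural cubic splines on the interval midpoints, with
  knots at quantiles of the death-count distribution over each time scale
  (sparse tails get fewer knots than event-dense regions);
* the period and cohort spline bases are projected orthogonal to the
  constant and linear functions of their midpoints, under a person-years
  weighted inner product, leaving pure-curvature columns;
* the drift enters as one column of centered calendar time.

With age basis dimension d_A (including intercept) and curvature dimensions
d_P - 2 and d_C - 2, the full design has rank d_A + 1 + (d_P-2) + (d_C-2);
the default d_A = d_P = d_C = 5 gives rank 12 and residual df 108 on a
15 x 8 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import LexisGrid, LexisTable, ValidationError

MODEL_NAMES = ("age", "age-drift", "age-cohort", "age-period-cohort", "age-period")

DEFAULT_REF_PERIOD = 1997.5   # midpoint of 1995-1999
DEFAULT_REF_COHORT = 1950.0   # midpoint (period - age) of the 1950-1954 birth cohort


def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis with K knots -> K columns incl. intercept.

    Standard truncated-power construction: columns are 1, x, and
    d_k(x) - d_{K-1}(x) for k = 1..K-2 with
    d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k).
    Linear beyond the boundary knots.
    """
    x = np.asarray(x, float)
    knots = np.sort(np.asarray(knots, float))
    K = knots.size
    if K < 3:
        raise ValidationError(f"need at least 3 knots, got {K}")
    if np.any(np.diff(knots) <= 0):
        raise ValidationError("knots must be distinct")

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[-1], 0, None) ** 3) / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def weighted_quantile_knots(x, weights, n_knots) -> np.ndarray:
    """Knots at weighted quantiles (probs (i - 0.5)/n) of x.

    Weights are typically cell death counts, so knots crowd where the events
    are. Falls back to evenly spaced points over the range when the weighted
    quantiles collapse (all events in few cells) or weights are degenerate.
    """
    x = np.asarray(x, float)
    w = np.asarray(weights, float)
    probs = (np.arange(1, n_knots + 1) - 0.5) / n_knots
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    if ws.sum() <= 0 or not np.all(np.isfinite(ws)):
        knots = np.quantile(np.unique(xs), probs)
    else:
        cdf = np.cumsum(ws) / ws.sum()
        knots = xs[np.searchsorted(cdf, probs, side="left").clip(0, xs.size - 1)]
    knots = np.unique(knots)
    if knots.size < n_knots:
        knots = np.linspace(x.min(), x.max(), n_knots)
    return knots


@dataclass
class DetrendedBasis:
    """A spline basis projected orthogonal to {1, midpoint} under a weighted
    inner product; evaluable at new midpoints via the stored projection."""

    knots: np.ndarray
    lin_coef: np.ndarray   # 2 x d: weighted projection of basis onto (1, t)
    rotation: np.ndarray   # d x (d-2): maps residual columns to a full-rank basis

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        M = natural_spline_basis(t, self.knots)
        X = np.column_stack([np.ones_like(t), t])
        return (M - X @ self.lin_coef) @ self.rotation

    @property
    def n_columns(self) -> int:
        return self.rotation.shape[1]


def detrend_basis(knots, t_cells, weights) -> DetrendedBasis:
    """Build the pure-curvature basis from spline knots, cell midpoints and
    cell weights (person-years by default; uniform when weights is None)."""
    t = np.asarray(t_cells, float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise ValidationError("detrending weights must be >= 0")
    M = natural_spline_basis(t, knots)
    X = np.column_stack([np.ones_like(t), t])
    sw = np.sqrt(w)
    lin_coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw[:, None] * M, rcond=None)
    R = M - X @ lin_coef
    # rotate residual columns onto their top d-2 principal directions
    _, s, Vt = np.linalg.svd(sw[:, None] * R, full_matrices=False)
    d = M.shape[1]
    keep = d - 2
    if keep < 1 or s[keep - 1] <= s[0] * 1e-10:
        raise ValidationError("curvature basis is rank deficient after detrending")
    rotation = Vt[:keep].T
    return DetrendedBasis(np.asarray(knots, float), lin_coef, rotation)


@dataclass
class APCDesign:
    """All design information for one Lexis table's APC model family."""

    grid: LexisGrid
    age_knots: np.ndarray
    period_basis: DetrendedBasis
    cohort_basis: DetrendedBasis
    ref_period: float = DEFAULT_REF_PERIOD
    ref_cohort: float = DEFAULT_REF_COHORT
    drift_axis: str = "cohort"

    # cached cell-level covariates, set in __post_init__
    age_cells: np.ndarray = field(init=False, repr=False)
    period_cells: np.ndarray = field(init=False, repr=False)
    cohort_cells: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.drift_axis not in ("cohort", "period"):
            raise ValidationError(f"drift_axis must be 'cohort' or 'period', got {self.drift_axis!r}")
        p, a = np.meshgrid(self.grid.period_midpoints, self.grid.age_midpoints)
        self.age_cells = a.ravel()
        self.period_cells = p.ravel()
        self.cohort_cells = (p - a).ravel()

    # --- column blocks -------------------------------------------------
    def age_block(self, a=None) -> np.ndarray:
        a = self.age_cells if a is None else np.atleast_1d(np.asarray(a, float))
        return natural_spline_basis(a, self.age_knots)

    def drift_column(self, p=None) -> np.ndarray:
        p = self.period_cells if p is None else np.atleast_1d(np.asarray(p, float))
        return (p - self.ref_period)[:, None]

    def period_block(self, p=None) -> np.ndarray:
        return self.period_basis(self.period_cells if p is None else p)

    def cohort_block(self, c=None) -> np.ndarray:
        return self.cohort_basis(self.cohort_cells if c is None else c)

    def matrix(self, model: str = "age-period-cohort") -> np.ndarray:
        """Cell-level design matrix (cells in row-major age x period order)."""
        if model not in MODEL_NAMES:
            raise ValidationError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
        blocks = [self.age_block()]
        if model != "age":
            blocks.append(self.drift_column())
        if model in ("age-cohort", "age-period-cohort"):
            blocks.append(self.cohort_block())
        if model in ("age-period", "age-period-cohort"):
            blocks.append(self.period_block())
        return np.column_stack(blocks)

    def column_slices(self, model: str = "age-period-cohort") -> dict:
        """Start/stop slices of each block in `matrix(model)`."""
        d_a = self.age_block(self.grid.age_midpoints[:1]).shape[1]
        slices = {"age": slice(0, d_a)}
        pos = d_a
        if model != "age":
            slices["drift"] = slice(pos, pos + 1)
            pos += 1
        if model in ("age-cohort", "age-period-cohort"):
            n = self.cohort_basis.n_columns
            slices["cohort"] = slice(pos, pos + n)
            pos += n
        if model in ("age-period", "age-period-cohort"):
            n = self.period_basis.n_columns
            slices["period"] = slice(pos, pos + n)
            pos += n
        return slices

    def rank(self, model: str = "age-period-cohort") -> int:
        return int(np.linalg.matrix_rank(self.matrix(model)))

    def residual_df(self, model: str = "age-period-cohort", n_cells: int | None = None) -> int:
        n = self.grid.n_ages * self.grid.n_periods if n_cells is None else n_cells
        return n - self.rank(model)


def build_design(
    grid: LexisGrid,
    deaths: np.ndarray | None = None,
    person_years: np.ndarray | None = None,
    npar_age: int = 5,
    npar_period: int = 5,
    npar_cohort: int = 5,
    ref_period: float = DEFAULT_REF_PERIOD,
    ref_cohort: float = DEFAULT_REF_COHORT,
    drift_axis: str = "cohort",
    weighted_detrend: bool = True,
) -> APCDesign:
    """Build the APC design for a grid.

    `npar_*` are spline dimensions including intercept and linear term
    (all >= 3); curvature blocks end up with npar - 2 columns. Knots sit at
    quantiles of the death counts over each time scale (uniform when deaths
    is None); detrending uses person-years weights unless
    ``weighted_detrend=False`` or person_years is None.
    """
    for name, v in (("npar_age", npar_age), ("npar_period", npar_period), ("npar_cohort", npar_cohort)):
        if v < 3:
            raise ValidationError(f"{name} must be >= 3, got {v}")
    if not (grid.period_midpoints[0] <= ref_period <= grid.period_midpoints[-1]):
        raise ValidationError(f"ref_period {ref_period} outside observed periods")
    p, a = np.meshgrid(grid.period_midpoints, grid.age_midpoints)
    a_cells, p_cells, c_cells = a.ravel(), p.ravel(), (p - a).ravel()
    if not (c_cells.min() <= ref_cohort <= c_cells.max()):
        raise ValidationError(f"ref_cohort {ref_cohort} outside observed cohorts")

    d = None if deaths is None else np.asarray(deaths, float).ravel()
    w = None
    if weighted_detrend and person_years is not None:
        w = np.asarray(person_years, float).ravel()

    age_knots = weighted_quantile_knots(a_cells, d if d is not None else np.ones_like(a_cells), npar_age)
    per_knots = weighted_quantile_knots(p_cells, d if d is not None else np.ones_like(p_cells), npar_period)
    coh_knots = weighted_quantile_knots(c_cells, d if d is not None else np.ones_like(c_cells), npar_cohort)

    period_basis = detrend_basis(per_knots, p_cells, w)
    cohort_basis = detrend_basis(coh_knots, c_cells, w)
    design = APCDesign(grid, age_knots, period_basis, cohort_basis,
                       ref_period=ref_period, ref_cohort=ref_cohort, drift_axis=drift_axis)

    expected = npar_age + 1 + (npar_period - 2) + (npar_cohort - 2)
    if design.rank("age-period-cohort") != expected:
        raise ValidationError(
            f"full design rank {design.rank('age-period-cohort')} != expected {expected}; "
            "check knots / detrending"
        )
    return design
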