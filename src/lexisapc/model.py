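"""Poisson APC fitting and estimable-function extraction.

`fit_poisson` maximizes the Poisson log-likelihood with a log link and a
log person-years offset (IRLS via statsmodels GLM); corrected death counts
may be non-integer, in which case the same deviance expression is read as a
quasi-likelihood. `apc_fit` fits the full age-drift-curvature design and
reports the estimable functions:

* the longitudinal age curve — fitted rates per 100,000 along the reference
  birth cohort;
* the drift — exponentiated annual trend, with Wald 95% CI;
* cohort relative risks — exp(drift x (c - c_ref) + curvature contrast),
  equal to 1 at the reference cohort (drift on the cohort axis, the
  default);
* period relative risks — residual, detrended RRs anchored at 1 at the
  reference period.

All intervals are delta-method (Wald) intervals on linear contrasts of the
coefficients, exponentiated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import APCDesign, build_design
from .grid import LexisGrid, LexisTable, ValidationError

log = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """IRLS failed to converge or the fit diverged (separation)."""


@dataclass
class PoissonFit:
    """Result of one Poisson GLM fit on Lexis cells."""

    params: np.ndarray
    cov: np.ndarray
    deviance: float
    df_resid: int
    fitted: np.ndarray
    n_iter: int = 0
    converged: bool = True
    boundary: bool = False


def poisson_deviance(deaths: np.ndarray, mu: np.ndarray) -> float:
    """2 * sum[D log(D/mu) - (D - mu)], with D log(D/mu) = 0 when D = 0."""
    d = np.asarray(deaths, float)
    mu = np.asarray(mu, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return float(2.0 * np.sum(term - (d - mu)))


def fit_poisson(
    X: np.ndarray,
    deaths: np.ndarray,
    person_years: np.ndarray,
    maxiter: int = 100,
    tol: float = 1e-10,
) -> PoissonFit:
    """Poisson log-link GLM with log(person_years) offset, by IRLS.

    Real-valued (corrected) deaths are accepted. Cells with zero
    person-years must be excluded by the caller. The covariance is the
    inverse observed information at the optimum; a tiny ridge (1e-8) is
    added only if the information matrix is singular, with a logged warning.
    """
    X = np.asarray(X, float)
    d = np.asarray(deaths, float).ravel()
    py = np.asarray(person_years, float).ravel()
    if np.any(py <= 0):
        raise ValidationError("person_years must be > 0 for all fitted cells")
    if np.any(d < 0):
        raise ValidationError("deaths must be >= 0")
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    df_resid = n - rank

    if d.sum() == 0.0:
        # likelihood boundary: MLE pushes all fitted means to 0 (intercept
        # -> -inf); return the limit instead of iterating into overflow
        return PoissonFit(
            params=np.full(p, np.nan), cov=np.full((p, p), np.nan),
            deviance=0.0, df_resid=df_resid, fitted=np.zeros(n),
            n_iter=0, converged=True, boundary=True,
        )

    offset = np.log(py)
    glm = sm.GLM(d, X, family=sm.families.Poisson(), offset=offset)
    res = glm.fit(maxiter=maxiter, tol=tol, tol_criterion="deviance")
    if not res.converged:
        raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations")
    if np.any(np.abs(res.params) > 1e3):
        log.warning("very large coefficients (max |b| = %.3g): possible separation",
                    np.abs(res.params).max())
    mu = res.fittedvalues
    # observed = expected information for the canonical log link
    info = X.T @ (mu[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        log.warning("singular information matrix; applying 1e-8 ridge")
        cov = np.linalg.inv(info + 1e-8 * np.eye(p))
    return PoissonFit(
        params=np.asarray(res.params), cov=cov,
        deviance=poisson_deviance(d, mu), df_resid=df_resid,
        fitted=np.asarray(mu), n_iter=int(res.fit_history["iteration"]),
        converged=bool(res.converged),
    )


def _exp_ci(est: np.ndarray, se: np.ndarray, scale: float = 1.0):
    lo = scale * np.exp(est - Z95 * se)
    hi = scale * np.exp(est + Z95 * se)
    return scale * np.exp(est), lo, hi


def _contrast_frame(L: np.ndarray, fit: PoissonFit, midpoints, scale: float = 1.0,
                    colname: str = "estimate") -> pd.DataFrame:
    est = L @ fit.params
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", L, fit.cov, L), 0.0))
    point, lo, hi = _exp_ci(est, se, scale)
    return pd.DataFrame({"midpoint": np.asarray(midpoints, float),
                         colname: point, "lo95": lo, "hi95": hi})


@dataclass
class APCFit:
    """Fitted APC model: estimable functions with Wald 95% intervals."""

    design: APCDesign
    fit: PoissonFit
    age_curve: pd.DataFrame      # midpoint, rate_per_100000, lo95, hi95
    period_rr: pd.DataFrame      # midpoint, rr, lo95, hi95
    cohort_rr: pd.DataFrame      # midpoint, rr, lo95, hi95
    drift: float
    drift_ci: tuple
    label: str = ""

    @property
    def deviance(self) -> float:
        return self.fit.deviance

    @property
    def df_resid(self) -> int:
        return self.fit.df_resid

    def fitted_rates(self) -> np.ndarray:
        """Fitted I x J rates per 100,000 person-years."""
        grid = self.design.grid
        eta = self.design.matrix("age-period-cohort") @ self.fit.params
        return 1e5 * np.exp(eta).reshape(grid.shape)


def apc_fit(table: LexisTable, design: APCDesign | None = None, **design_options) -> APCFit:
    """Fit the full APC model to a Lexis table and extract effects.

    Default references: period 1995-1999 (midpoint 1997.5) and birth cohort
    1950-1954 (midpoint 1950). `design_options` are forwarded to
    :func:`lexisapc.design.build_design` when no design is given.
    """
    grid = table.grid
    if design is None:
        design = build_design(grid, table.deaths, table.person_years, **design_options)
    X = design.matrix("age-period-cohort")
    fit = fit_poisson(X, table.deaths.ravel(), table.person_years.ravel())
    if fit.boundary:
        raise ConvergenceError("cannot extract APC effects from an all-zero table")
    sl = design.column_slices("age-period-cohort")
    p_cols = X.shape[1]

    a_mid = grid.age_midpoints
    p_mid = grid.period_midpoints
    c_mid = grid.cohort_midpoints
    p_ref, c_ref = design.ref_period, design.ref_cohort
    drift_on_cohort = design.drift_axis == "cohort"

    # drift: the coefficient on centered calendar time, per year
    L_drift = np.zeros((1, p_cols))
    L_drift[0, sl["drift"]] = 1.0
    ddf = _contrast_frame(L_drift, fit, [0.0])
    drift, dlo, dhi = float(ddf["estimate"][0]), float(ddf["lo95"][0]), float(ddf["hi95"][0])

    # cohort RR: curvature contrast vs reference cohort, plus drift if the
    # drift is allocated to the cohort axis
    C = design.cohort_basis(c_mid) - design.cohort_basis([c_ref])
    Lc = np.zeros((c_mid.size, p_cols))
    Lc[:, sl["cohort"]] = C
    if drift_on_cohort:
        Lc[:, sl["drift"]] = (c_mid - c_ref)[:, None]
    cohort_rr = _contrast_frame(Lc, fit, c_mid, colname="rr")

    # period RR: curvature contrast vs reference period (+ drift if on period axis)
    P = design.period_basis(p_mid) - design.period_basis([p_ref])
    Lp = np.zeros((p_mid.size, p_cols))
    Lp[:, sl["period"]] = P
    if not drift_on_cohort:
        Lp[:, sl["drift"]] = (p_mid - p_ref)[:, None]
    period_rr = _contrast_frame(Lp, fit, p_mid, colname="rr")

    # longitudinal age curve: fitted rate along the reference cohort; the
    # anchoring constants (curvature at the references) are folded in so that
    # rate_ij = age_curve * period_rr * cohort_rr exactly
    La = np.zeros((a_mid.size, p_cols))
    La[:, sl["age"]] = design.age_block(a_mid)
    La[:, sl["period"]] = np.repeat(design.period_basis([p_ref]), a_mid.size, axis=0)
    La[:, sl["cohort"]] = np.repeat(design.cohort_basis([c_ref]), a_mid.size, axis=0)
    if drift_on_cohort:
        # at cohort c_ref, calendar time is a + c_ref
        La[:, sl["drift"]] = (a_mid + c_ref - p_ref)[:, None]
    age_curve = _contrast_frame(La, fit, a_mid, scale=1e5, colname="rate_per_100000")

    return APCFit(design, fit, age_curve, period_rr, cohort_rr,
                  drift, (dlo, dhi), label=table.label)


def classify_trend(drift: float, ci: tuple) -> str:
    """Label a fitted drift: 'upward', 'downward' or 'stationary'.

    The call follows the confidence interval: upward when the whole 95% CI
    exceeds 1, downward when it lies below 1, stationary when it contains 1.
    """
    lo, hi = float(ci[0]), float(ci[1])
    if not (0 < lo <= hi):
        raise ValidationError(f"invalid confidence interval ({lo}, {hi})")
    if drift <= 0:
        raise ValidationError(f"drift must be positive, got {drift}")
    if lo > 1.0:
        return "upward"
    if hi < 1.0:
        return "downward"
    return "stationary"
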