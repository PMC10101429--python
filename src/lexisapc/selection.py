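"""Nested deviance ladder and likelihood-ratio tests for APC submodels.

Six models are fitted in the conventional ladder order

    age, age-drift, age-cohort, age-period-cohort, age-period, age-drift

(the age-drift row appears twice: the drift-cohort and drift-period
parameterizations give identical fits, and both rows are reported). Five
likelihood-ratio comparisons read off which nonlinear terms matter:

1. age vs age-drift           — any linear trend at all;
2. age-drift vs age-cohort    — nonlinear cohort effect;
3. age-cohort vs full APC     — nonlinear period effect, given cohort;
4. full APC vs age-period     — nonlinear cohort effect, given period;
5. age-period vs age-drift    — nonlinear period effect.

Each p-value is the upper chi-square tail of the deviance difference at the
difference in residual df, placed on the row of the *larger* model of the
pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import APCDesign, build_design
from .grid import LexisTable, ValidationError
from .model import PoissonFit, fit_poisson

LADDER = ("age", "age-drift", "age-cohort", "age-period-cohort", "age-period", "age-drift")

#: (reduced, full) pairs of the five nested comparisons, in ladder order
COMPARISONS = (
    ("age", "age-drift"),
    ("age-drift", "age-cohort"),
    ("age-cohort", "age-period-cohort"),
    ("age-period", "age-period-cohort"),
    ("age-drift", "age-period"),
)

INTERPRETATION = {
    ("age", "age-drift"): "linear period+cohort trend (drift)",
    ("age-drift", "age-cohort"): "nonlinear cohort effect",
    ("age-cohort", "age-period-cohort"): "nonlinear period effect, given cohort",
    ("age-period", "age-period-cohort"): "nonlinear cohort effect, given period",
    ("age-drift", "age-period"): "nonlinear period effect",
}


def lrt(dev_reduced: float, df_reduced: int, dev_full: float, df_full: int) -> float:
    """Likelihood-ratio p-value for nested Poisson fits.

    Upper chi-square tail of (dev_reduced - dev_full) at df_reduced - df_full
    degrees of freedom.
    """
    if df_reduced <= df_full:
        raise ValidationError(
            f"models are not nested: reduced df {df_reduced} <= full df {df_full}"
        )
    delta = dev_reduced - dev_full
    if delta < -1e-8:
        raise ValidationError(
            f"reduced-model deviance {dev_reduced} below full-model deviance {dev_full}"
        )
    return float(stats.chi2.sf(max(delta, 0.0), df_reduced - df_full))


@dataclass
class DevianceTable:
    """The six-row submodel ladder with the five nested LRT p-values."""

    rows: pd.DataFrame  # columns: model, df, deviance, p_value, comparison
    fits: dict          # model name -> PoissonFit

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    p_values: dict = None  # (reduced, full) -> p

    def best_model(self) -> str:
        """'age-period-cohort' when every nonlinear term is significant at 5%
        (comparisons 2-5); otherwise the smallest model not rejected."""
        nonlinear = [self.p_values[c] for c in COMPARISONS[1:]]
        if all(v < 0.05 for v in nonlinear):
            return "age-period-cohort"
        # fall back: walk the forward chain and stop at the first non-significant step
        chain = ("age", "age-drift", "age-cohort", "age-period-cohort")
        for reduced, full in zip(chain[:-1], chain[1:]):
            dev_r = float(self.rows.loc[self.rows.model == reduced, "deviance"].iloc[0])
            df_r = int(self.rows.loc[self.rows.model == reduced, "df"].iloc[0])
            dev_f = float(self.rows.loc[self.rows.model == full, "deviance"].iloc[0])
            df_f = int(self.rows.loc[self.rows.model == full, "df"].iloc[0])
            if lrt(dev_r, df_r, dev_f, df_f) >= 0.05:
                return reduced
        return "age-period-cohort"


def fit_ladder(table: LexisTable, design: APCDesign | None = None, **design_options) -> DevianceTable:
    """Fit the six-model ladder on one Lexis table.

    All submodels share the bases of the full design, so residual df depend
    only on the grid and basis dimensions, never on the counts.
    """
    if design is None:
        design = build_design(table.grid, table.deaths, table.person_years, **design_options)
    d = table.deaths.ravel()
    py = table.person_years.ravel()
    fits: dict[str, PoissonFit] = {}
    for model in set(LADDER):
        fits[model] = fit_poisson(design.matrix(model), d, py)

    records = []
    pvals = {}
    for reduced, full in COMPARISONS:
        pvals[(reduced, full)] = lrt(
            fits[reduced].deviance, fits[reduced].df_resid,
            fits[full].deviance, fits[full].df_resid,
        )
    # p-value shown on the row of the larger model of each ladder-adjacent pair
    row_p = {
        1: pvals[("age", "age-drift")],
        2: pvals[("age-drift", "age-cohort")],
        3: pvals[("age-cohort", "age-period-cohort")],
        4: pvals[("age-period", "age-period-cohort")],
        5: pvals[("age-drift", "age-period")],
    }
    row_cmp = {1: "vs age", 2: "vs age-drift", 3: "vs age-cohort",
               4: "vs age-period-cohort", 5: "vs age-period"}
    for idx, model in enumerate(LADDER):
        records.append({
            "model": model,
            "df": fits[model].df_resid,
            "deviance": fits[model].deviance,
            "p_value": row_p.get(idx, np.nan),
            "comparison": row_cmp.get(idx, ""),
        })
    rows = pd.DataFrame.from_records(records)
    return DevianceTable(rows, fits, pvals)
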