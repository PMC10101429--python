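"""CSV readers and writers for the package's typed objects.

All files are UTF-8, comma-separated, '.' decimal separator, with a header
row. Schemas are validated strictly: a missing column raises a
:class:`~lexisapc.grid.ValidationError` naming it, and locale-formatted
decimals ("1,2") are rejected with guidance rather than silently coerced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .correction import CorrectionFactors, DeathRecord
from .grid import LexisGrid, LexisTable, ValidationError
from .standardize import StandardPopulation

LEXIS_COLUMNS = ("age_low", "period_low", "deaths", "person_years", "label")
FACTOR_COLUMNS = ("decade", "region", "factor")
STANDARD_COLUMNS = ("age_low", "weight")
RECORD_COLUMNS = ("icd_code", "icd_revision", "age", "year", "region")


def _read_csv(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, path, columns) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        bad = out[col].str.contains(",", na=False)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValidationError(
                f"{path}: column '{col}' row {row} uses a comma decimal separator "
                f"({out[col][bad.idxmax()]!r}); use '.' as the decimal separator"
            )
        try:
            out[col] = pd.to_numeric(out[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: column '{col}' is not numeric: {exc}") from exc
    return out


def write_lexis(table: LexisTable, path) -> None:
    """Long-format Lexis CSV: age_low, period_low, deaths, person_years, label."""
    grid = table.grid
    rows = []
    for i, alo in enumerate(grid.age_lower_bounds):
        for j, plo in enumerate(grid.period_lower_bounds):
            rows.append((alo, plo, table.deaths[i, j], table.person_years[i, j], table.label))
    pd.DataFrame(rows, columns=LEXIS_COLUMNS).to_csv(path, index=False)


def read_lexis(path) -> LexisTable:
    df = _numeric(_read_csv(path, LEXIS_COLUMNS), path,
                  ("age_low", "period_low", "deaths", "person_years"))
    ages = np.sort(df["age_low"].unique())
    periods = np.sort(df["period_low"].unique())
    if len(df) != len(ages) * len(periods):
        raise ValidationError(
            f"{path}: {len(df)} rows do not form a complete "
            f"{len(ages)} x {len(periods)} grid"
        )
    grid = LexisGrid(
        age_lower_bounds=tuple(ages),
        period_lower_bounds=tuple(periods),
        age_width=float(ages[1] - ages[0]),
        period_width=float(periods[1] - periods[0]),
    )
    deaths = np.zeros(grid.shape)
    py = np.zeros(grid.shape)
    ai = {a: i for i, a in enumerate(ages)}
    pj = {p: j for j, p in enumerate(periods)}
    for _, row in df.iterrows():
        i, j = ai[row["age_low"]], pj[row["period_low"]]
        deaths[i, j] = row["deaths"]
        py[i, j] = row["person_years"]
    labels = df["label"].unique()
    return LexisTable(grid, deaths, py, label=str(labels[0]) if len(labels) else "")


def read_factors(path) -> CorrectionFactors:
    df = _numeric(_read_csv(path, FACTOR_COLUMNS), path, ("factor",))
    return CorrectionFactors({
        (str(r["decade"]), str(r["region"])): float(r["factor"]) for _, r in df.iterrows()
    })


def write_factors(factors: CorrectionFactors, path) -> None:
    rows = [(d, r, f) for (d, r), f in sorted(factors.factors.items())]
    pd.DataFrame(rows, columns=FACTOR_COLUMNS).to_csv(path, index=False)


def read_standard(path) -> StandardPopulation:
    df = _numeric(_read_csv(path, STANDARD_COLUMNS), path, STANDARD_COLUMNS)
    return StandardPopulation(df["age_low"].to_numpy(), df["weight"].to_numpy())


def read_records(path) -> list:
    df = _numeric(_read_csv(path, RECORD_COLUMNS), path, ("icd_revision", "age", "year"))
    return [
        DeathRecord(
            icd_code=str(r["icd_code"]), icd_revision=int(r["icd_revision"]),
            age=float(r["age"]), year=int(r["year"]), region=str(r["region"]),
        )
        for _, r in df.iterrows()
    ]
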