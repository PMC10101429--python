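"""Rectification of suicide death records.

Two steps, applied to registry counts before any rate is computed:

1. Reclassification: deaths coded as intoxication of undetermined intent
   (ICD-9 E980-E982 / ICD-10 Y10-Y19) and as sequelae of self-inflicted
   injury (E959 / Y87) are added to the deaths coded as suicide
   (E950-E958 / X60-X84), cell by cell.
2. Underreporting correction: the resulting counts are multiplied by
   decade x region coverage factors (>= 1) that offset incomplete death
   registration. Corrected counts are fractional and kept as reals.

For firearm suicide only step 2 applies. The firearm ICD subset is not a
registry convention with a single authoritative definition; the default
(X72-X74 and E955.0-E955.4) is configurable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .grid import LexisGrid, LexisTable, ValidationError

log = logging.getLogger(__name__)

CATEGORIES = ("suicide", "firearm_suicide", "undetermined_intoxication", "sequelae", "other")

#: default firearm subset: (revision, normalized code prefix)
DEFAULT_FIREARM_CODES = {
    10: ("X72", "X73", "X74"),
    9: ("E9550", "E9551", "E9552", "E9553", "E9554"),
}

_CODE_RE = {
    9: re.compile(r"^(E\d{3}\d?|V\d{2}\d?|\d{3}\d*)$"),
    10: re.compile(r"^[A-Z]\d{2}\d*$"),
}


def _normalize(code: str) -> str:
    """Uppercase and strip the dot separator: 'e950.1' -> 'E9501'."""
    return code.strip().upper().replace(".", "")


def classify_icd(code: str, revision: int, firearm_codes: dict | None = None) -> str:
    """Map an ICD-9 or ICD-10 cause-of-death code to a cause category.

    Categories are exhaustive and mutually exclusive; firearm suicide takes
    precedence over the general suicide range. Range checks compare the
    3-character stem; 4-character subcodes inherit the stem's category
    unless the firearm subset says otherwise. Comparison is case-insensitive
    and ignores a dot separator.
    """
    if revision not in (9, 10):
        raise ValidationError(f"unknown ICD revision {revision!r}; expected 9 or 10")
    if not code or not code.strip():
        raise ValidationError("empty ICD code")
    norm = _normalize(code)
    if not _CODE_RE[revision].match(norm):
        raise ValidationError(f"malformed ICD-{revision} code {code!r}")
    firearm = (firearm_codes or DEFAULT_FIREARM_CODES).get(revision, ())
    if any(norm == f or norm.startswith(f) for f in firearm):
        return "firearm_suicide"
    letter = norm[0]
    if revision == 9:
        # ICD-9 external-cause stems are E + 3 digits; anything else is 'other'
        if letter != "E":
            return "other"
        num = int(norm[1:4])
        if 950 <= num <= 958:
            return "suicide"
        if 980 <= num <= 982:
            return "undetermined_intoxication"
        if num == 959:
            return "sequelae"
        return "other"
    # ICD-10 stems are a letter plus 2 digits
    num = int(norm[1:3])
    if letter == "X" and 60 <= num <= 84:
        return "suicide"
    if letter == "Y" and 10 <= num <= 19:
        return "undetermined_intoxication"
    if letter == "Y" and num == 87:
        return "sequelae"
    return "other"


@dataclass(frozen=True)
class DeathRecord:
    """One line-listed death."""

    icd_code: str
    icd_revision: int
    age: float
    year: int
    region: str = ""

    def __post_init__(self):
        if self.age < 0:
            raise ValidationError(f"negative age {self.age}")
        if self.icd_revision not in (9, 10):
            raise ValidationError(f"unknown ICD revision {self.icd_revision}")


@dataclass
class AggregationResult:
    """Per-category count tables plus the records that fell outside the grid."""

    tables: dict
    n_dropped: int

    def __getitem__(self, category: str) -> LexisTable:
        return self.tables[category]


def aggregate_records(
    records,
    grid: LexisGrid,
    firearm_codes: dict | None = None,
) -> AggregationResult:
    """Bin line-listed deaths into one count table per cause category.

    Records younger than the first age bound, or dated outside the period
    range, are dropped and counted (reported, not fatal). Ages beyond the
    last bound fall into the open interval.
    """
    age_edges = np.asarray(grid.age_lower_bounds, float)
    per_edges = np.asarray(grid.period_lower_bounds, float)
    counts = {c: np.zeros(grid.shape) for c in CATEGORIES}
    dropped = 0
    for rec in records:
        if rec.age < age_edges[0]:
            dropped += 1
            continue
        if not (per_edges[0] <= rec.year < per_edges[-1] + grid.period_width):
            dropped += 1
            continue
        if not grid.open_age and rec.age >= age_edges[-1] + grid.age_width:
            dropped += 1
            continue
        i = min(int(np.searchsorted(age_edges, rec.age, side="right")) - 1, grid.n_ages - 1)
        j = int(np.searchsorted(per_edges, rec.year, side="right")) - 1
        cat = classify_icd(rec.icd_code, rec.icd_revision, firearm_codes)
        counts[cat][i, j] += 1
    if dropped:
        log.info("aggregate_records: dropped %d record(s) outside the grid", dropped)
    tables = {
        c: LexisTable(grid, counts[c], np.ones(grid.shape), label=c) for c in CATEGORIES
    }
    return AggregationResult(tables, dropped)


def reclassify_total_suicide(
    suicide: LexisTable, undetermined: LexisTable, sequelae: LexisTable
) -> LexisTable:
    """Cellwise sum of suicide, undetermined-intoxication and sequelae counts."""
    for other in (undetermined, sequelae):
        if other.grid != suicide.grid:
            raise ValidationError("grids of the three tables must match")
    total = suicide.deaths + undetermined.deaths + sequelae.deaths
    return LexisTable(suicide.grid, total, suicide.person_years.copy(), label=suicide.label)


@dataclass
class CorrectionFactors:
    """Decade x region multiplicative coverage factors, all >= 1.

    Missing (decade, region) pairs default to 1.0 with a logged warning, so
    partially-specified factor tables degrade to no correction rather than
    failing.
    """

    factors: dict = field(default_factory=dict)

    def __post_init__(self):
        for key, f in self.factors.items():
            if not np.isfinite(f) or f < 1.0:
                raise ValidationError(f"correction factor {f} for {key} is < 1")

    def factor_for(self, decade: str, region: str) -> float:
        key = (decade, region)
        if key not in self.factors:
            log.warning("no correction factor for %s; using 1.0", key)
            return 1.0
        return self.factors[key]


def decade_of(period_lower_bound: float) -> str:
    """Decade label of a period, from its lower bound (1985-89 -> '1980s')."""
    return f"{int(period_lower_bound) // 10 * 10}s"


def apply_underreporting(
    table: LexisTable, factors: CorrectionFactors, region: str
) -> LexisTable:
    """Multiply each period's deaths by its decade x region coverage factor."""
    out = table.deaths.copy()
    for j, lo in enumerate(table.grid.period_lower_bounds):
        out[:, j] *= factors.factor_for(decade_of(lo), region)
    return LexisTable(table.grid, out, table.person_years.copy(), label=table.label)
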