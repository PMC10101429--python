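"""Scenario orchestration: correction -> rates -> ladder -> APC fit -> trend.

A *scenario* is one cause mode (total or firearm suicide) in one locality.
For total suicide the correction stage first adds undetermined-intent
intoxication and sequelae deaths to the suicide counts and then applies the
decade x region underreporting factors; for firearm suicide only the
underreporting factors apply. The corrected table then flows through direct
standardization, the six-model deviance ladder, the full APC fit and the
drift-based trend call. Every stage's outputs are written as CSV and the
whole run is deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import (CorrectionFactors, aggregate_records,
                         apply_underreporting, reclassify_total_suicide)
from .grid import LexisGrid, LexisTable, ValidationError
from .io import read_factors, read_lexis, read_records, read_standard, write_lexis
from .model import APCFit, apc_fit, classify_trend
from .selection import DevianceTable, fit_ladder
from .standardize import (StandardPopulation, age_specific_rates,
                          moving_average, standardized_series, who_world_standard)

log = logging.getLogger(__name__)


@dataclass
class ModelOptions:
    """Tunable options of the APC design, mirrored by config keys."""

    ref_period: float = 1997.5
    ref_cohort: float = 1950.0
    npar_age: int = 5
    npar_period: int = 5
    npar_cohort: int = 5
    drift_axis: str = "cohort"
    weighted_detrend: bool = True

    def as_design_kwargs(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScenarioConfig:
    """One scenario: inputs, cause mode, model options, output directory."""

    label: str
    mode: str = "total"                 # 'total' | 'firearm'
    region: str = ""
    lexis_path: str | None = None       # pre-aggregated counts + person-years
    records_path: str | None = None     # line-listed deaths (alternative input)
    person_years_path: str | None = None  # exposures, required with records
    factors_path: str | None = None     # underreporting factors; 1.0 if absent
    standard_path: str | None = None    # standard population; WHO if absent
    output_dir: str = "."
    seed: int = 0
    model: ModelOptions = field(default_factory=ModelOptions)

    def __post_init__(self):
        if self.mode not in ("total", "firearm"):
            raise ValidationError(f"mode must be 'total' or 'firearm', got {self.mode!r}")
        if self.lexis_path is None and self.records_path is None:
            raise ValidationError("scenario needs either lexis_path or records_path")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = ModelOptions(**raw.pop("model", {}))
        return cls(model=model, **raw)


@dataclass
class ScenarioResult:
    """Everything one scenario produces."""

    config: ScenarioConfig
    corrected: LexisTable
    rates: np.ndarray
    standardized: pd.Series
    smoothed: pd.Series
    ladder: DevianceTable
    fit: APCFit
    trend: str


def _corrected_counts(config: ScenarioConfig, factors: CorrectionFactors) -> LexisTable:
    if config.records_path is not None:
        if config.person_years_path is None:
            raise ValidationError("records input requires person_years_path")
        exposure = read_lexis(config.person_years_path)
        agg = aggregate_records(read_records(config.records_path), exposure.grid)
        if config.mode == "firearm":
            raw = agg["firearm_suicide"]
        else:
            suicide_all = agg["suicide"].with_deaths(
                agg["suicide"].deaths + agg["firearm_suicide"].deaths
            )
            raw = reclassify_total_suicide(
                suicide_all, agg["undetermined_intoxication"], agg["sequelae"]
            )
        raw = raw.with_person_years(exposure.person_years).copy(label=config.label)
    else:
        raw = read_lexis(config.lexis_path).copy(label=config.label)
        # pre-aggregated input is taken as already reclassified for total mode
    return apply_underreporting(raw, factors, config.region)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Execute one scenario end to end and write all artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    factors = read_factors(config.factors_path) if config.factors_path else CorrectionFactors({})
    std = read_standard(config.standard_path) if config.standard_path else who_world_standard()

    corrected = _corrected_counts(config, factors)
    log.info("[%s] correction: total deaths %.2f on %s grid",
             config.label, corrected.deaths.sum(), corrected.grid.shape)

    rates = age_specific_rates(corrected)
    series = standardized_series(corrected, std)
    smoothed = moving_average(series, window=3)
    log.info("[%s] standardized rate range %.2f-%.2f per 100,000",
             config.label, series.values.min(), series.values.max())

    kwargs = config.model.as_design_kwargs()
    ladder = fit_ladder(corrected, **kwargs)
    fit = apc_fit(corrected, **kwargs)
    trend = classify_trend(fit.drift, fit.drift_ci)
    log.info("[%s] APC deviance %.2f on %d df; drift %.4f (%.4f-%.4f): %s",
             config.label, fit.deviance, fit.df_resid, fit.drift, *fit.drift_ci, trend)

    _write_outputs(out, config, corrected, rates, series, smoothed, ladder, fit, trend)
    return ScenarioResult(config, corrected, rates, smoothed=smoothed.to_series(),
                          standardized=series.to_series(), ladder=ladder, fit=fit, trend=trend)


def _write_outputs(out, config, corrected, rates, series, smoothed, ladder, fit, trend):
    label = config.label
    write_lexis(corrected, out / f"{label}_corrected.csv")

    grid = corrected.grid
    rate_rows = [
        (grid.age_group_label(i), grid.period_label(j), rates[i, j])
        for i in range(grid.n_ages) for j in range(grid.n_periods)
    ]
    pd.DataFrame(rate_rows, columns=["age_group", "period", "rate_per_100000"]).to_csv(
        out / f"{label}_age_specific_rates.csv", index=False)

    pd.DataFrame({"period_midpoint": series.labels, "standardized_rate": series.values}).to_csv(
        out / f"{label}_standardized_rates.csv", index=False)
    pd.DataFrame({"period_midpoint": smoothed.labels, "smoothed_rate": smoothed.values}).to_csv(
        out / f"{label}_smoothed_rates.csv", index=False)

    ladder.to_frame().to_csv(out / f"{label}_deviance_ladder.csv", index=False)

    effects = pd.concat([
        fit.age_curve.rename(columns={"rate_per_100000": "estimate"}).assign(axis="age"),
        fit.period_rr.rename(columns={"rr": "estimate"}).assign(axis="period"),
        fit.cohort_rr.rename(columns={"rr": "estimate"}).assign(axis="cohort"),
    ])[["axis", "midpoint", "estimate", "lo95", "hi95"]]
    effects.to_csv(out / f"{label}_effects.csv", index=False)

    run_log = {
        "package": "lexisapc",
        "version": __version__,
        "label": label,
        "mode": config.mode,
        "seed": config.seed,
        "model_options": config.model.as_design_kwargs(),
        "deviance": fit.deviance,
        "df_resid": fit.df_resid,
        "drift": fit.drift,
        "drift_ci": list(fit.drift_ci),
        "trend": trend,
        "irls_iterations": fit.fit.n_iter,
    }
    with open(out / f"{label}_run.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)


def run_scenarios(configs) -> dict:
    """Run several scenarios; a failure aborts only its own scenario."""
    results, failures = {}, {}
    for cfg in configs:
        try:
            results[cfg.label] = run_scenario(cfg)
        except Exception as exc:  # noqa: BLE001 - stage-tagged, other scenarios proceed
            log.error("[%s] failed: %s", cfg.label, exc)
            failures[cfg.label] = exc
    if failures:
        log.warning("%d scenario(s) failed: %s", len(failures), sorted(failures))
    return results
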