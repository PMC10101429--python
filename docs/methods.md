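# Methods

## The model

`lexisapc` analyses mortality counts on a Lexis table: deaths θ_ij and
person-years N_ij cross-classified by 5-year age group *i* (I = 15 groups,
10–14 … 80+) and 5-year calendar period *j* (J = 8, 1980–84 … 2015–19).
Birth cohorts run along the K = I + J − 1 = 22 diagonals, with midpoints
c = p − a spanning 1900 … 2005. Counts are modelled as Poisson with a log
link and log person-years offset:

    log E[θ_ij] = log N_ij + μ + α_i + β_j + γ_k ,   k = j − i + I .

Because cohort = period − age exactly, the three effects are collinear and
only *estimable functions* of them are reported:

* **age curve** — fitted rates per 100,000 along the reference birth cohort
  (the longitudinal age curve);
* **drift** — the sum of the period and cohort linear slopes, exponentiated
  to a multiplicative change per calendar year;
* **curvatures** — the detrended, nonlinear parts of the period and cohort
  effects, shown as relative risks (RR) anchored at 1 in the reference
  period (1995–1999, midpoint 1997.5) and reference cohort (1950–1954,
  midpoint 1950).

These quantities are invariant to the unidentified linear reallocation
between age, period and cohort, which is the entire point of the
parameterization.

### Design construction

Smooth effects use natural cubic splines on interval midpoints
(truncated-power construction; K knots give K columns including intercept
and linear term; linear beyond the boundary knots). Knots sit at quantiles
(probabilities (i − ½)/K) of the death-count distribution along each time
scale, so knots crowd where the events are; with no counts supplied, at
uniform-weight quantiles of the cell midpoints. The period and cohort bases
are then projected orthogonal to {1, midpoint} under a person-years-weighted
inner product (unweighted optional) and rotated to their top d − 2 principal
directions, leaving pure-curvature columns. The drift enters as a single
column of calendar time centered at the reference period.

Default dimensions are d_A = d_P = d_C = 5 (configurable: `npar_age`,
`npar_period`, `npar_cohort`), giving model ranks 5 / 6 / 9 / 12 / 9 for the
age, age-drift, age-cohort, full APC and age-period models, hence residual
df 115 / 114 / 111 / 108 / 111 on the 120-cell default grid. Residual df are
computed as cells-with-exposure minus the numerical rank of the design, so
they depend only on the grid and basis options, never on the counts.

### Fitting and inference

Fitting is iteratively reweighted least squares (via `statsmodels` GLM) with
deviance convergence tolerance 1e-10 and a 100-iteration cap; the covariance
is the inverse observed information at the optimum (observed = expected for
the canonical log link), with a 1e-8 ridge applied only on a singular
information matrix, logged. Corrected (fractional) death counts are accepted;
the deviance 2Σ[D log(D/μ̂) − (D − μ̂)] (with D log(D/μ̂) = 0 at D = 0) is
evaluated as written, a quasi-likelihood reading. An all-zero response is a
likelihood-boundary case (intercept → −∞) and is returned as its limit:
deviance 0, fitted means 0, flagged `boundary`. Suspiciously large
coefficients (|b| > 1000) trigger a separation warning.

All intervals are Wald (delta-method) intervals on linear contrasts of the
coefficients, exponentiated. At the reference period and cohort the contrast
is identically zero, so the RR is exactly 1 with zero-width CI.

### Drift allocation and trend calls

The drift is attached to the cohort axis by default (`drift_axis="cohort"`):
cohort RRs are exp(drift·(c − c_ref) + curvature contrast) and period RRs
are residual, detrended RRs hovering near 1. The alternative allocation is
available and changes only the presentation, never the fit: the fitted cell
rates, deviance and drift estimate are invariant. The decomposition is
exact — age curve × period RR × cohort RR reproduces every fitted cell rate,
because the anchoring constants (curvature evaluated at the references) are
folded into the age curve.

A trend is **upward** when the drift's 95% CI lies wholly above 1,
**downward** when wholly below 1, and **stationary** when the CI contains 1.
The classifier validates only interval orientation, not that the point
estimate lies inside the interval, so externally reported (estimate, CI)
triplets can be classified as printed.

### Model selection

Six models are fitted in the conventional ladder order (age; age-drift;
age-cohort; full APC; age-period; age-drift again — the drift-cohort and
drift-period parameterizations fit identically and both rows are emitted).
Five likelihood-ratio tests compare nested pairs: age vs age-drift (any
linear trend), age-drift vs age-cohort (nonlinear cohort), age-cohort vs APC
(nonlinear period given cohort), age-period vs APC (nonlinear cohort given
period), and age-drift vs age-period (nonlinear period). P-values are upper
χ² tails of deviance differences at the df difference. The full APC model is
labelled best when all four nonlinear comparisons are significant at 5%;
otherwise selection walks the forward chain and stops at the first
non-significant step.

A calibration caveat: the default event-quantile knots are data-adaptive,
which makes nested LRTs slightly anti-conservative (the χ² reference assumes
a design fixed before seeing the data). Calibration studies in the test
suite therefore pre-specify the design from the grid alone; applied analyses
keeping the default should read borderline p-values with this in mind.

## Record correction

Two steps precede any rate. (1) Reclassification: deaths coded as
intoxication of undetermined intent (ICD-9 E980–E982, ICD-10 Y10–Y19) and as
sequelae of self-inflicted injury (E959, Y87) are added cellwise to suicide
deaths (E950–E958, X60–X84). (2) Underreporting: counts are multiplied by
decade × region coverage factors ≥ 1 (decade taken from the period's lower
bound, so 1985–89 belongs to the 1980s); missing pairs default to 1 with a
warning. Firearm scenarios skip step 1. The firearm ICD subset is an
external convention, not a registry fact; the configurable default is
X72–X74 and E955.0–E955.4. Code matching is case-insensitive, ignores a dot
separator, compares 3-character stems (ICD-9) / letter + 2 digits (ICD-10),
and 4-character subcodes inherit the stem's category unless the firearm
subset overrides. Correction-factor values themselves are study inputs (a
synthetic example table ships under `examples/data/`); no published factor
table is bundled.

## Standardization and smoothing

Age-specific rates are 100 000·θ/N. Direct standardization is the weighted
mean Σ_a w_a r_a with the bundled WHO world standard population; when the
grid truncates the age range, weights are collapsed onto the grid's groups
(the open 80+ interval absorbs the tail) and renormalized to sum to 1 —
the renormalization convention over a truncated range is a package choice,
so standardized levels are comparable within, not across, conventions.
Smoothing is a centered 3-term moving average that shortens the series at
each end; padding was rejected because it fabricates data. Annual as well as
five-year series are supported by the same code path.

## The synthetic-data generator

The generator mirrors the fitted model: deaths ~ Poisson(N·exp(η)) with
η = baseline + age curve + drift·(p − p₀) + period curvature + cohort
curvature, p₀ the first period midpoint. Supplied curvature sequences are
re-detrended (OLS on their midpoints) so drift is, by construction, the
unique linear trend of the surface; consequently η is invariant to adding
any linear-in-midpoint term to a curvature input. Age midpoints are lower
bound + 2.5 with the open 80+ interval at 82.5; cohort midpoints are
period − age, which yields the 1900–2005 span exactly. One integer seed
fixes a table; replicate studies advance it as seed + replicate index.

Defaults emulate male suicide mortality at national-registry scale: baseline
9 deaths per 100 000 person-years, rates rising ≈3-fold over the age range,
drift exp(0.008) ≈ +0.8%/year, mild sinusoidal period and cohort curvature,
10⁶ person-years per cell. What the generator does *not* emulate —
overdispersion, registration artefacts, covariates, spatial structure —
bounds what passing tests show: they demonstrate correctness of the
machinery under the model's own assumptions, not robustness of the model on
real registries.

## Validation problem sizes

Structural checks (grid geometry, df ladder, trend rule) are exact and
instant. Stochastic checks use the generator's default conditions: drift
recovery and CI coverage over 200 replicate tables at 10⁶ person-years per
cell; null calibration of the age-vs-APC LRT over 500 no-trend simulations
against χ²₇; IRLS-vs-Newton deviance agreement to 1e-6 on 20 random small
tables. The whole suite runs in well under a minute on one CPU.

## Known limitations

* Wald intervals only; profile-likelihood intervals are not implemented.
* No overdispersion modelling: with real registry data the Poisson deviance
  per df typically exceeds 1 and the stated CIs are then too narrow.
* The open-ended 80+ age interval is treated as a regular 5-year band at
  midpoint 82.5; if mortality keeps rising steeply past 85 this understates
  the top age effect.
* The grid starts at age 10–14 although analyses of adult suicide often
  define the population from age 14 up; the generator and correction stage
  follow the grid.
* Best-model selection is a fixed 5% rule on the nested tests, not an
  information-criterion search.
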