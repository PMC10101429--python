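"""Draw a synthetic Lexis table with known age-period-cohort structure.

The generator is the exact mirror of the fitted model: Poisson counts with
mean N_ij * exp(eta_ij), where eta decomposes into an age curve, an annual
drift and detrended period/cohort curvatures.
"""

from lexisapc import LexisGrid, SimConfig, default_truth, simulate_lexis

grid = LexisGrid()  # 15 five-year age groups (10-14 ... 80+) x 8 periods (1980-84 ... 2015-19)
truth = default_truth(grid)  # ~9/100,000 baseline, rising with age, +0.8%/year drift
table = simulate_lexis(SimConfig(grid, truth, person_years_per_cell=1e6, seed=7))

print(f"grid: {grid.n_ages} age groups x {grid.n_periods} periods "
      f"-> {grid.n_cohorts} birth cohorts ({grid.cohort_midpoints[0]:.0f}-"
      f"{grid.cohort_midpoints[-1]:.0f})")
print(f"total deaths drawn: {table.deaths.sum():.0f} "
      f"over {table.person_years.sum():.3g} person-years")
print(f"crude rate: {1e5 * table.deaths.sum() / table.person_years.sum():.2f} per 100,000")
# The cohort count I + J - 1 = 22 is forced by the Lexis geometry: each
# diagonal of the age x period grid is one birth cohort.
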