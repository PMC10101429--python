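"""Nested deviance analysis: which temporal effects does the data support?

Six models are fitted (age; age-drift twice, once per parameterization;
age-cohort; full APC; age-period) and five likelihood-ratio tests compare
adjacent pairs. Residual df depend only on the grid and basis dimensions:
115 / 114 / 111 / 108 / 111 / 114 under the defaults.
"""

from lexisapc import LexisGrid, SimConfig, default_truth, fit_ladder, simulate_lexis

grid = LexisGrid()
table = simulate_lexis(SimConfig(grid, default_truth(grid), 1e7, seed=7))

ladder = fit_ladder(table)
print(ladder.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"\nbest model: {ladder.best_model()}")
# Each p-value reads: does the row's model fit significantly better than the
# model it is compared against? Small p on every nonlinear comparison keeps
# the full APC model.
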