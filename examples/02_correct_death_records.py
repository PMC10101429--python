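"""Two-step correction of suicide death records.

Step 1 reclassifies deaths of undetermined intent (Y10-Y19 / E980-E982) and
sequelae of self-inflicted injury (Y87 / E959) into the suicide counts.
Step 2 inflates each decade's counts by a region-specific underreporting
factor (here a synthetic example table).
"""

from pathlib import Path

from lexisapc import DeathRecord, LexisGrid, aggregate_records, \
    apply_underreporting, reclassify_total_suicide
from lexisapc.io import read_factors

grid = LexisGrid()
records = [
    DeathRecord("X70", 10, age=27, year=1983, region="demo-region"),   # suicide (hanging)
    DeathRecord("X72", 10, age=35, year=1996, region="demo-region"),   # firearm suicide
    DeathRecord("Y10", 10, age=41, year=1996, region="demo-region"),   # undetermined intent
    DeathRecord("Y87", 10, age=52, year=2004, region="demo-region"),   # sequelae
    DeathRecord("E9509", 9, age=33, year=1988, region="demo-region"),  # ICD-9 suicide
    DeathRecord("I21", 10, age=60, year=2001, region="demo-region"),   # unrelated cause
]
agg = aggregate_records(records, grid)
suicide_all = agg["suicide"].with_deaths(
    agg["suicide"].deaths + agg["firearm_suicide"].deaths)
total = reclassify_total_suicide(
    suicide_all, agg["undetermined_intoxication"], agg["sequelae"])
print(f"raw suicide counts: {suicide_all.deaths.sum():.0f}; "
      f"after reclassification: {total.deaths.sum():.0f}")

factors = read_factors(Path(__file__).parent / "data" / "synthetic_correction_factors.csv")
corrected = apply_underreporting(total, factors, region="demo-region")
print(f"after underreporting correction: {corrected.deaths.sum():.2f} "
      "(fractional: counts were multiplied by decade-specific factors >= 1)")
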