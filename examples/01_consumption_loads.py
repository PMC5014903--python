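"""Regional drug consumption -> annual mass -> expected influent band.

Defined-daily-dose (DDD) statistics are the smallest unit of consumption
data usually available.  This example converts the bundled 2011 records to
annual consumed mass and apportions the regional mass to a small treatment
plant (12,000 of 1.25 M people, 200 L wastewater per person and day) to get
an expected raw-sewage concentration band from the excretion interval.
"""

from pharmfate import datasets
from pharmfate.exposure import load_estimates, load_table

records = datasets.consumption_records()
estimates = load_estimates(
    records,
    datasets.compound_registry(),
    population_served=12_000,
    region_population=datasets.REGION_POPULATION,
    wastewater_L_per_capita_day=datasets.WASTEWATER_L_PER_CAPITA_DAY,
)

table = load_table(records, estimates)
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print()
print(
    "consumption_kg_per_year is N_DDD x DDD(mg) x 1e-6 rounded to whole kg; "
    "the expected-influent columns bracket the raw-sewage concentration "
    "(ng/L) implied by the low/high literature excretion fractions — wide "
    "bands (e.g. furosemide) reflect genuinely conflicting excretion data."
)
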