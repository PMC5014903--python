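"""Removal efficiency from influent/effluent pairs, censoring included.

Removal = (C_in - C_out) / C_in x 100.  The example computes a few
hand-built pairs — including a negative removal (effluent above influent,
a real phenomenon caused by deconjugation) and a below-LOD effluent that
turns the efficiency into a lower bound — then prints the survey-style
removal matrix for the bundled reference catchment.
"""

from pharmfate import (
    InfluentEffluentPair,
    Qualifier,
    Quantity,
    Unit,
    datasets,
    pairs_from_measurements,
    removal_efficiency,
    removal_table,
    simulate,
)

examples = [
    InfluentEffluentPair("demo", "well-removed",
                         Quantity(1000.0, Unit.NG_PER_L),
                         Quantity(110.0, Unit.NG_PER_L)),
    InfluentEffluentPair("demo", "released",
                         Quantity(400.0, Unit.NG_PER_L),
                         Quantity(500.0, Unit.NG_PER_L)),
    InfluentEffluentPair("demo", "below-LOD",
                         Quantity(1000.0, Unit.NG_PER_L),
                         Quantity(50.0, Unit.NG_PER_L, Qualifier.LESS_THAN)),
]
for pair in examples:
    res = removal_efficiency(pair)
    print(f"{pair.compound:>12}: {res.table_value:>4} %  flags={sorted(f.value for f in res.flags)}")

print()
dataset = simulate(datasets.reference_catchment())
results = [removal_efficiency(p) for p in pairs_from_measurements(list(dataset.measurements))]
print(removal_table(results).to_string())
print()
print(
    "Columns are (plant, sample type); cells are integer percent. Negative "
    "cells mean the plant released more than it received; '≥' cells are "
    "lower bounds from censored effluents."
)
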