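# pharmfate

Source-to-sink exposure and aquatic-risk pipeline for pharmaceutical
residues in a surface-water catchment.

Pharmaceuticals enter rivers, lakes and wetlands mainly through
wastewater-treatment plants (WWTPs) and landfill leachate.  Monitoring
surveys of such systems produce small, heterogeneous tables — regional
consumption statistics, influent/effluent pairs, surface-water and sediment
concentrations with censored values ("<LOD", ">8000 ng/kg"), literature
ecotoxicity endpoints — and the scientific conclusions rest on a short
chain of arithmetic over them.  `pharmfate` implements that chain as a
tested, reusable library:

* **Consumption loads** — annual mass from defined-daily-dose (DDD)
  statistics, `mass [kg/y] = N_DDD × DDD[mg] × 10⁻⁶`, and an expected
  influent concentration band from population apportionment and the
  (often conflicting) excretion-fraction interval.
* **WWTP removal** — `η [%] = (C_in − C_out)/C_in × 100` per compound,
  plant and sample type, with negative removals preserved and censored
  effluents reported as `≥` bounds.
* **Sediment–water partitioning** — `K_d = C_sed/C_w` (L/kg) from
  co-located pairs and `K_oc = K_d/f_TOC`.
* **Risk quotients** — `PNEC = endpoint/AF` (AF 10 for NOEC, 20 for LOEC),
  `RQ = MEC/PNEC`, reported to one significant figure with a
  `risk_unlikely` / `potential_risk` / `unassessable` verdict.
* **Synthetic catchment simulator** — a seeded steady-state network
  (river → WWTP → channel → lake, plus landfill) with known removal,
  K_d, dilution, lognormal measurement noise and LOD censoring, and a
  recovery harness that quantifies estimator error against the truth.

All arithmetic runs on unit-aware, censoring-aware `Quantity` values: a
ratio of censored numbers carries the correct bound direction (an exact
value over a "<LOD" denominator is a ">" result; conflicting bounds are
indeterminate, never silently numeric).

The package ships the tables of a six-compound survey of a southern-Swedish
wetland catchment (atenolol, bendroflumethiazide, carbamazepine,
diclofenac, furosemide, oxazepam; sampling points SP1–SP7) as its built-in
fixture family, in `pharmfate.datasets`.

## Worked example

```python
from pharmfate import datasets
from pharmfate.risk import risk_results, risk_table

results = risk_results(datasets.lake_measurements(),
                       datasets.tox_endpoints(), site="SP7")
print(risk_table(results).to_string(index=False))
```

prints (abridged):

```
           compound  mec_ng_L endpoint_type  pnec_ng_L        rq  rq_reported       verdict
           atenolol       331          NOEC      1e+05   0.00331        0.003 risk_unlikely
bendroflumethiazide       0.7          None        NaN       NaN          NaN  unassessable
      carbamazepine       161          NOEC       2500    0.0644         0.06 risk_unlikely
         diclofenac       119          NOEC    1.5e+05 0.0007933       0.0008 risk_unlikely
         furosemide       100          NOEC   1.56e+04   0.00641        0.006 risk_unlikely
           oxazepam       115          LOEC        500      0.23          0.2 risk_unlikely
```

Each row divides the measured lake concentration by the PNEC derived from
the most sensitive chronic endpoint.  Every assessable quotient is far
below 1 — adverse single-substance effects in the lake are unlikely —
while bendroflumethiazide has no usable ecotoxicity study and is flagged
unassessable rather than dropped.  Mixture ("cocktail") effects are
explicitly outside what an RQ can say.

The `examples/` directory holds one short narrative script per capability
(consumption loads, removal, partitioning, risk, simulation + recovery);
each builds its own small input and explains the numbers it prints.

## Command line

A thin CLI wraps the library for shell use:

```sh
pharmfate fixtures --out fixtures/          # write the bundled tables
pharmfate run --config config.yaml --out out/
pharmfate removal --measurements m.csv --out removal.csv
pharmfate risk --measurements m.csv --endpoints e.csv --site SP7
pharmfate simulate --seed 42 --out sim/
```

`pharmfate run` executes all four stages and writes `load_estimates.csv`,
`removal_table.csv`, `partition_results.csv`, `risk_table.csv`, a
deterministic Markdown report and a MANIFEST.

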