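# Methods

This note documents the models, conventions and design choices behind
`pharmfate`, and what the synthetic-data tests do and do not demonstrate
about real monitoring data.

## Quantities, units and censoring

All concentrations and masses are `Quantity` values: a non-negative number,
a unit, and a censoring qualifier.  Canonical internal units are ng/L for
aqueous concentrations, ng/kg dry weight for sediment, and kg for annual
masses — the units monitoring reports print most often; every I/O boundary
converts to and from them.  Conversion factors are exact powers of ten
applied as integer multiplication or division, so conversions round-trip
at machine precision.

Qualifiers distinguish six states: `exact`, strict bounds `less_than` /
`greater_than`, non-strict bounds `at_most` / `at_least`, and
`not_detected`.  `not_detected` is deliberately not a synonym for
`less_than`: surveys report absences with no reporting limit at all, and a
value-less non-detect refuses arithmetic instead of contributing a silent
zero.  With a limit attached it behaves as `less_than(limit)`.  The strict
and non-strict forms are stored separately (reports use both typographies)
but treated identically in arithmetic.

Every downstream statistic is a ratio, so censoring propagates through one
algebra: the numerator contributes its own bound direction, the denominator
the inverse of its; agreeing directions keep the bound (strictness is
contagious), conflicting directions yield `indeterminate` plus a warning.
The full 6×6 table is pinned by an exhaustive test against a hand-written
oracle.  One deliberate asymmetry: removal-efficiency results normalise
bounds to the non-strict `at_least`/`at_most` form (`≥95 %`), the style
used in treatment-efficiency tables, while the raw ratio preserves
strictness.

## Consumption loads

`mass = N_DDD × DDD[mg] × 10⁻⁶ kg/y`; table output rounds half-up to whole
kg.  The expected influent concentration apportions the regional mass to a
plant by population share and dilutes into its wastewater volume:

    C = mass × (served/region) × f_exc × 10¹² / (served × V × 365)  [ng/L]

Region population (default 1,250,000) and per-capita wastewater production
(default 200 L/person/day) are explicit configuration values, logged and
echoed in the report header — they are modelling bridges, not
observations.  Excretion fractions are stored as intervals because the
clinical literature genuinely conflicts (furosemide spans "minute amounts"
to 90 % unchanged); the expected influent is therefore a low/mid/high band
and the comparison against measured influent is a ratio, never a
pass/fail.  A compound without excretion data returns an explicit
"unavailable" marker, not zero.

## Removal efficiency

`η = (C_in − C_out)/C_in × 100`, computed in difference form so that
`η(C, C) = 0` exactly and round percentages stay exact in float.  Negative
efficiencies are preserved and flagged (`negative_removal`): effluent can
exceed influent through deconjugation of metabolites or desorption from
particles.  Efficiency is undefined (an error, not NaN) when the influent
is zero or a non-detect.  Grab samples pair only with grab samples of the
same plant, 24-h composites only with composites.  No hydraulic-retention-
time lag correction is applied to grab pairs — a known limitation of
single-grab surveys that the report states rather than hides.  Table cells
round to integer percent; the API keeps full precision.

## Partitioning

`K_d = C_sed/C_w` from one co-located sediment/water pair per site and
compound — single-pair estimation, not regression across sites, because a
survey has one pair per site.  `K_oc = K_d/f_TOC` with the TOC fraction
carried on the sediment measurement.  Sediment concentrations are dry-
weight; no porosity or bulk-density correction is applied.

Censored sediment values are common (">8000 ng/kg" means the extraction
saturated or the calibration topped out).  The default
`censored_as_point: true` reads such bounds as point estimates — the
convention under which published coefficients are reproducible — and flags
the result `censored_input`; setting it false propagates the bound to a
">"-qualified K_d, which is the honest-uncertainty view.  Both behaviours
are tested.

## Risk quotients

`PNEC = endpoint/AF` with AF 10 for NOEC and 20 for LOEC; the factor table
is user-extensible but deliberately ships only these two chronic factors —
the acute 100/1000 scheme and species-coverage rules of full regulatory
guidance are out of scope for a screening chain.  The most sensitive
endpoint is the one with the lowest derived PNEC (ties broken by source
string for determinism).  `RQ = MEC/PNEC`; verdicts use a single threshold
at 1 with only two classes plus `unassessable`, because a screening
quotient supports no finer banding.  Reported quotients are rounded to one
significant figure, half away from zero, via decimal arithmetic
(`0.00331 → 0.003`).  One bundled inconsistency is preserved rather than
patched: the surveyed oxazepam quotient was printed as 0.24, but its own
inputs give 115/(10 000/20) = 0.23 (reported 0.2 at one significant
figure); the package reports the computed chain.

## Synthetic catchment generator

The simulator emulates a single-time-point monitoring campaign over a
steady-state network.  Node order is a topological order by construction
(upstream references must point to earlier nodes), which excludes cycles.
Propagation rules per compound:

* WWTP: effluent = influent × (100 − removal)/100; influent levels are
  truth parameters, per plant and sample type.
* Junctions/lakes/channels: flow-weighted mixing `C = ΣQᵢCᵢ/ΣQᵢ`, then an
  optional `dilution_factor ≥ 1` for unmeasured clean inflow (outflow is
  scaled up correspondingly, so contaminant mass is conserved and
  concentrations are monotone non-increasing along source-free paths).
* Sediment: an equilibrium observation `C_sed = K_d × C_w × (f_TOC/f_TOC_ref)`,
  not a sink — the water column loses mass only to explicit removal and
  dilution.  The TOC scaling encodes the empirical association between
  organic carbon and sorption; the recovery harness divides it back out so
  the estimator targets the true K_d at any node.

Measurement noise is multiplicative lognormal, `value × exp(σZ)`, default
σ = 0.1 — roughly the analytical CV of replicate LC-MS/MS determinations,
and the natural error model for positive concentrations.  Values below the
LOD are replaced by `< LOD` censored quantities.  All randomness flows
through one named numpy `Generator` seeded with a single integer; a spec
plus seed reproduces byte-identical CSV/JSON output, and one draw is
consumed per emitted measurement even at σ = 0 so the stream alignment does
not depend on the noise level.

What passing recovery tests show: the estimators are unbiased at σ = 0 and
well-behaved under the stated noise (median |removal error| < 5 percentage
points at true removal 50 % over 200 replicate catchments at σ = 0.1;
geometric-mean K_d recovery within 10 %).  What they do not show: the
generator has no temporal dynamics, no in-stream degradation, no flow
variability, no matrix effects and no correlated censoring, so these
results bound estimator error under idealised conditions only — real
grab-sample surveys add sources of error the simulator does not emulate.

The bundled reference catchment is a σ = 0 scenario whose truth parameters
equal the surveyed removal matrix and distribution coefficients; its flows
and influent levels are invented within the concentration ranges the survey
describes and are labelled as invented in the emitted `truth.json`.  Its
LOD is set to zero so a complete-removal plant shows an exact 100 % rather
than a "≥" bound (both encodings are representable; input data decides).

## Numerical and formatting choices

* Half-up rounding for table integers and for one-significant-figure
  quotients, via `decimal` to avoid binary-float surprises.
* Removal results are exact-qualified only when both inputs are exact;
  recovery reports `None` estimates with flags for censored/indeterminate
  cases instead of numbers.
* CSV I/O is UTF-8, comma-separated, "." decimal; an explicit
  `decimal_comma` flag parses European exports ("11.000" = 11 000) — the
  convention is never guessed from context.  Row-level validation collects
  every error with file and line number before raising.

## Problem sizes

The test and acceptance workloads are deliberately desk-scale: property
suites run on ≥1000 randomized cases, recovery studies on 200 seeded
single-plant catchments, and the full fixture pipeline on the seven-site,
six-compound survey network.  These sizes make the whole suite run in
seconds while leaving every statistical margin (e.g. the 5-point median
error bound) non-trivially exercised.

## Known limitations

No pH-dependent speciation or activity corrections; no isotherm or kinetic
sorption models; no metabolite or transformation-product tracking; no
mixture toxicity (a concentration-addition module would be a natural
extension but single-substance quotients cannot be summed without one);
no probabilistic (SSD) risk assessment; no hydrological routing.
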