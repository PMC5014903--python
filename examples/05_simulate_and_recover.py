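"""Synthetic catchment: generate noisy data, re-estimate the truth.

A seeded steady-state simulator propagates each compound from WWTP influent
through removal, dilution and sediment equilibrium, then adds multiplicative
lognormal measurement noise and left-censors against the LOD.  Running the
removal and partitioning estimators on the synthetic measurements and
comparing against the generator's truth quantifies estimator error under a
known noise level.
"""

import numpy as np

from pharmfate.simulate import recover, simple_catchment, simulate

print("single catchment, sigma = 0.1, seed = 42:")
dataset = simulate(simple_catchment(noise_sigma=0.1, seed=42))
rec = recover(dataset)
for r in rec.removal:
    print(f"  removal  {r.plant}/{r.compound}: estimate {r.estimate:.1f} %, "
          f"truth {r.truth:.0f} %, error {r.error:+.1f} points")
for r in rec.kd:
    print(f"  K_d      {r.site}/{r.compound}: estimate {r.estimate:.1f}, "
          f"truth {r.truth:.0f} L/kg")

errors = []
for seed in range(200):
    rec = recover(simulate(simple_catchment(noise_sigma=0.1, seed=seed)))
    errors.extend(abs(r.error) for r in rec.removal)
print()
print(f"200 replicate catchments at true removal 50 %: median |error| = "
      f"{np.median(errors):.2f} percentage points")
print(
    "With 10 % lognormal noise on both influent and effluent the removal "
    "estimate is typically within ~5 points of truth; at sigma = 0 the "
    "recovery is exact, which is the estimators' correctness check."
)
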