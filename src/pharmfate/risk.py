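"""Aquatic risk characterisation: PNEC derivation and risk quotients.

The predicted no-effect concentration (PNEC) is derived from the most
sensitive chronic ecotoxicological endpoint by an assessment factor:
10 for a NOEC, 20 for a LOEC (user-extensible).  The risk quotient is

    RQ = MEC / PNEC

with the measured environmental concentration (MEC) in surface water.
RQ < 1 is read as "adverse single-substance effects unlikely"; compounds
without any usable endpoint are reported as unassessable rather than
silently dropped.  Reported quotients are rounded to one significant
figure, the convention of screening-level assessments.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .quantities import Dimension, Qualifier, Quantity, Unit, convert
from .records import EndpointType, Matrix, Measurement, ToxEndpoint

#: default assessment factors per endpoint type
DEFAULT_ASSESSMENT_FACTORS: dict[EndpointType, float] = {
    EndpointType.NOEC: 10.0,
    EndpointType.LOEC: 20.0,
}


class Verdict(str, enum.Enum):
    RISK_UNLIKELY = "risk_unlikely"
    POTENTIAL_RISK = "potential_risk"
    UNASSESSABLE = "unassessable"


def round_1sf(x: float) -> float:
    """Round a positive number to one significant figure, half away from
    zero (0.00331 -> 0.003, 0.0644 -> 0.06, 0.25 -> 0.3)."""
    if x <= 0:
        raise ValueError("round_1sf requires a positive value")
    exponent = Decimal(repr(x)).adjusted()
    quantum = Decimal(1).scaleb(exponent)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def pnec(
    endpoint: ToxEndpoint,
    assessment_factors: dict[EndpointType, float] | None = None,
) -> float:
    """PNEC in ng/L: endpoint value divided by its assessment factor."""
    factors = assessment_factors or DEFAULT_ASSESSMENT_FACTORS
    try:
        af = factors[endpoint.endpoint_type]
    except KeyError as exc:
        raise ValueError(
            f"no assessment factor configured for {endpoint.endpoint_type}"
        ) from exc
    value_ng_L = convert(endpoint.value, Unit.NG_PER_L).value
    assert value_ng_L is not None  # enforced by ToxEndpoint validation
    return value_ng_L / af


def most_sensitive_endpoint(
    endpoints: list[ToxEndpoint],
    assessment_factors: dict[EndpointType, float] | None = None,
) -> ToxEndpoint | None:
    """The endpoint with the lowest derived PNEC (most conservative); ties
    broken by the earliest-sorting source string.  ``None`` for an empty
    collection (unassessable)."""
    if not endpoints:
        return None
    return min(
        endpoints,
        key=lambda e: (pnec(e, assessment_factors), e.source),
    )


@dataclass(frozen=True)
class RiskResult:
    compound: str
    mec: Quantity | None
    endpoint: ToxEndpoint | None
    assessment_factor: float | None
    pnec_ng_L: float | None
    rq: float | None
    rq_reported: float | None
    verdict: Verdict
    qualifier: Qualifier = Qualifier.EXACT


def risk_quotient(
    mec: Quantity,
    pnec_ng_L: float,
    endpoint: ToxEndpoint,
    assessment_factors: dict[EndpointType, float] | None = None,
) -> RiskResult:
    """RQ = MEC / PNEC; a censored MEC propagates its qualifier to the RQ."""
    if pnec_ng_L <= 0:
        raise ValueError("PNEC must be positive")
    if mec.unit.dimension is not Dimension.AQUEOUS:
        raise ValueError(f"MEC must be aqueous, got {mec.unit.label}")
    mec_ng_L = convert(mec, Unit.NG_PER_L)
    if mec_ng_L.value is None:
        raise ValueError("MEC non-detect without a reporting limit")
    rq = mec_ng_L.value / pnec_ng_L
    factors = assessment_factors or DEFAULT_ASSESSMENT_FACTORS
    verdict = Verdict.RISK_UNLIKELY if rq < 1.0 else Verdict.POTENTIAL_RISK
    return RiskResult(
        compound=endpoint.compound,
        mec=mec,
        endpoint=endpoint,
        assessment_factor=factors[endpoint.endpoint_type],
        pnec_ng_L=pnec_ng_L,
        rq=rq,
        rq_reported=round_1sf(rq) if rq > 0 else 0.0,
        verdict=verdict,
        qualifier=mec.arithmetic_qualifier() if mec.is_censored else Qualifier.EXACT,
    )


def assess_compound(
    compound: str,
    mec: Quantity | None,
    endpoints: list[ToxEndpoint],
    assessment_factors: dict[EndpointType, float] | None = None,
) -> RiskResult:
    """Screening assessment of one compound: pick the most sensitive
    endpoint, derive the PNEC, compute the RQ.  Missing endpoint or missing
    MEC both yield an unassessable verdict."""
    endpoint = most_sensitive_endpoint(endpoints, assessment_factors)
    if endpoint is None or mec is None:
        return RiskResult(
            compound=compound,
            mec=mec,
            endpoint=endpoint,
            assessment_factor=None,
            pnec_ng_L=None if endpoint is None else pnec(endpoint, assessment_factors),
            rq=None,
            rq_reported=None,
            verdict=Verdict.UNASSESSABLE,
        )
    return risk_quotient(mec, pnec(endpoint, assessment_factors), endpoint,
                         assessment_factors)


def risk_results(
    measurements: list[Measurement],
    endpoints: list[ToxEndpoint],
    *,
    site: str,
    compounds: list[str] | None = None,
    assessment_factors: dict[EndpointType, float] | None = None,
) -> list[RiskResult]:
    """Assess every compound measured in surface water at ``site`` (or the
    explicit compound list), matching each to its endpoints."""
    mecs = {
        m.compound: m.quantity
        for m in measurements
        if m.site == site and m.matrix is Matrix.SURFACE_WATER
    }
    by_compound: dict[str, list[ToxEndpoint]] = {}
    for e in endpoints:
        by_compound.setdefault(e.compound, []).append(e)
    names = compounds if compounds is not None else sorted(mecs)
    return [
        assess_compound(
            name, mecs.get(name), by_compound.get(name, []), assessment_factors
        )
        for name in names
    ]


def risk_table(results: list[RiskResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        mec_ng_L = (
            None if r.mec is None else convert(r.mec, Unit.NG_PER_L).value
        )
        rows.append(
            {
                "compound": r.compound,
                "mec_ng_L": mec_ng_L,
                "endpoint_type": None if r.endpoint is None else r.endpoint.endpoint_type.value,
                "endpoint_value_ng_L": (
                    None
                    if r.endpoint is None
                    else convert(r.endpoint.value, Unit.NG_PER_L).value
                ),
                "af": r.assessment_factor,
                "pnec_ng_L": r.pnec_ng_L,
                "rq": r.rq,
                "rq_reported": r.rq_reported,
                "verdict": r.verdict.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "mec_ng_L",
            "endpoint_type",
            "endpoint_value_ng_L",
            "af",
            "pnec_ng_L",
            "rq",
            "rq_reported",
            "verdict",
        ],
    )
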