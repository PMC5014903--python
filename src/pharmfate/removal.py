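"""Wastewater-treatment-plant removal efficiency.

Removal is the concentration difference between influent and effluent water
divided by the influent concentration:

    efficiency [%] = (C_in - C_out) / C_in x 100.

Negative efficiencies are real and preserved (deconjugation of metabolites
or desorption from particles can raise effluent above influent).  A censored
effluent ("<LOD") makes the efficiency a lower bound and is reported with an
``at_least`` qualifier; removal is undefined when the influent itself is a
non-detect or zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .quantities import (
    CensoringError,
    Dimension,
    Qualifier,
    Quantity,
    UndefinedRatioError,
    ratio,
)
from .records import Matrix, Measurement, SampleType


class UndefinedRemovalError(ValueError):
    """Influent zero or not detected: removal cannot be defined."""


class AmbiguousPairError(ValueError):
    """More than one influent/effluent pair maps to the same table cell."""


class RemovalFlag(str, enum.Enum):
    NEGATIVE_REMOVAL = "negative_removal"
    CENSORED = "censored"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class InfluentEffluentPair:
    plant: str
    compound: str
    influent: Quantity
    effluent: Quantity
    sample_type: SampleType = SampleType.GRAB

    def __post_init__(self) -> None:
        for side, q in (("influent", self.influent), ("effluent", self.effluent)):
            if q.unit.dimension is not Dimension.AQUEOUS:
                raise ValueError(
                    f"{self.plant}/{self.compound}: {side} must be an aqueous "
                    f"concentration, got {q.unit.label}"
                )


# efficiency = 100 * (1 - C_out/C_in): an upper bound on the ratio is a lower
# bound on the efficiency.  Removal results use the non-strict at_least /
# at_most style ("≥95 %") regardless of the strictness of the input bound.
_INVERTED = {
    Qualifier.EXACT: Qualifier.EXACT,
    Qualifier.LESS_THAN: Qualifier.AT_LEAST,
    Qualifier.AT_MOST: Qualifier.AT_LEAST,
    Qualifier.GREATER_THAN: Qualifier.AT_MOST,
    Qualifier.AT_LEAST: Qualifier.AT_MOST,
    Qualifier.INDETERMINATE: Qualifier.INDETERMINATE,
}


@dataclass(frozen=True)
class RemovalResult:
    plant: str
    compound: str
    sample_type: SampleType
    efficiency_percent: float
    qualifier: Qualifier = Qualifier.EXACT
    flags: frozenset[RemovalFlag] = frozenset()

    @property
    def table_value(self) -> str:
        """Integer-percent cell in reporting style: ``89``, ``≥95``, ``-34``."""
        rounded = int(math.floor(self.efficiency_percent + 0.5))
        if self.qualifier is Qualifier.INDETERMINATE:
            return f"{rounded}?"
        prefix = {
            Qualifier.EXACT: "",
            Qualifier.AT_LEAST: "≥",
            Qualifier.AT_MOST: "≤",
        }[self.qualifier]
        return f"{prefix}{rounded}"


def removal_efficiency(pair: InfluentEffluentPair) -> RemovalResult:
    """Removal efficiency of one influent/effluent pair, full precision.

    Raises :class:`UndefinedRemovalError` when the influent is zero or not
    detected.
    """
    influent = pair.influent
    if influent.qualifier is Qualifier.NOT_DETECTED:
        raise UndefinedRemovalError(
            f"{pair.plant}/{pair.compound}: influent not detected; removal "
            "is undefined"
        )
    if influent.value is None or influent.value <= 0:
        raise UndefinedRemovalError(
            f"{pair.plant}/{pair.compound}: influent must be positive"
        )
    try:
        r = ratio(pair.effluent, influent)
    except (UndefinedRatioError, CensoringError) as exc:
        raise UndefinedRemovalError(str(exc)) from exc

    # difference form keeps efficiency(C, C) == 0 and round values exact
    c_in = influent.canonical().value
    c_out = pair.effluent.canonical().value
    efficiency = (c_in - c_out) / c_in * 100.0
    qualifier = _INVERTED[r.qualifier]

    flags = set()
    if pair.influent.is_censored or pair.effluent.is_censored:
        flags.add(RemovalFlag.CENSORED)
    if qualifier is Qualifier.INDETERMINATE:
        flags.add(RemovalFlag.INDETERMINATE)
    if efficiency < 0 and qualifier in (Qualifier.EXACT, Qualifier.AT_MOST):
        flags.add(RemovalFlag.NEGATIVE_REMOVAL)

    return RemovalResult(
        plant=pair.plant,
        compound=pair.compound,
        sample_type=pair.sample_type,
        efficiency_percent=efficiency,
        qualifier=qualifier,
        flags=frozenset(flags),
    )


def pairs_from_measurements(
    measurements: list[Measurement],
) -> list[InfluentEffluentPair]:
    """Match influent and effluent measurements by (site, compound,
    sample_type).  Duplicate matrices for a key raise
    :class:`AmbiguousPairError`; unmatched singles are skipped."""
    buckets: dict[tuple, dict[Matrix, Measurement]] = {}
    for m in measurements:
        if m.matrix not in (Matrix.INFLUENT, Matrix.EFFLUENT):
            continue
        key = (m.site, m.compound, m.sample_type)
        bucket = buckets.setdefault(key, {})
        if m.matrix in bucket:
            raise AmbiguousPairError(
                f"duplicate {m.matrix.value} measurement for "
                f"{key[0]}/{key[1]} ({key[2].value})"
            )
        bucket[m.matrix] = m
    pairs = []
    for (site, compound, sample_type), bucket in buckets.items():
        if Matrix.INFLUENT in bucket and Matrix.EFFLUENT in bucket:
            pairs.append(
                InfluentEffluentPair(
                    plant=site,
                    compound=compound,
                    influent=bucket[Matrix.INFLUENT].quantity,
                    effluent=bucket[Matrix.EFFLUENT].quantity,
                    sample_type=sample_type,
                )
            )
    return pairs


def removal_table(results: list[RemovalResult]) -> pd.DataFrame:
    """Compound x (plant, sample_type) matrix of integer-percent cells with
    ``NA`` for missing pairs.  Duplicate results for one cell raise
    :class:`AmbiguousPairError`."""
    cells: dict[tuple[str, tuple[str, str]], RemovalResult] = {}
    for res in results:
        key = (res.compound, (res.plant, res.sample_type.value))
        if key in cells:
            raise AmbiguousPairError(
                f"two removal results for compound {res.compound!r} in column "
                f"{key[1]}: {cells[key]} and {res}"
            )
        cells[key] = res

    compounds = sorted({c for c, _ in cells})
    columns = sorted({col for _, col in cells})
    data = {
        col: [
            cells[(c, col)].table_value if (c, col) in cells else "NA"
            for c in compounds
        ]
        for col in columns
    }
    frame = pd.DataFrame(data, index=pd.Index(compounds, name="compound"))
    frame.columns = pd.MultiIndex.from_tuples(columns, names=["plant", "sample_type"])
    return frame
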