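"""Sediment-water partitioning.

The distribution coefficient of a compound between sediment and the
overlying water column is estimated from one co-located pair:

    K_d [L/kg] = C_sediment [ng/kg dw] / C_water [ng/L],

and normalised by the sediment's total-organic-carbon fraction to

    K_oc = K_d / f_TOC.

Monitoring sediments are often reported as lower bounds (">8000 ng/kg");
by default such values are read as point estimates so printed coefficients
are reproduced (``censored_as_point=True``), but honest bound propagation
through the ratio algebra is one switch away.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .quantities import Dimension, Qualifier, Quantity, ratio
from .records import Matrix, Measurement


class MissingTocError(ValueError):
    """K_oc requested without a usable TOC fraction."""


@dataclass(frozen=True)
class PartitionResult:
    site: str
    compound: str
    kd_L_per_kg: float
    qualifier: Qualifier
    c_sediment: Quantity
    c_water: Quantity
    toc_fraction: float | None = None
    censored_input: bool = False

    @property
    def koc_L_per_kg(self) -> float | None:
        if self.toc_fraction is None:
            return None
        return koc(self)


def kd(
    c_sediment: Quantity,
    c_water: Quantity,
    *,
    site: str = "",
    compound: str = "",
    toc_fraction: float | None = None,
    censored_as_point: bool = True,
) -> PartitionResult:
    """Distribution coefficient from one sediment/water pair.

    With ``censored_as_point`` (the default) censored inputs contribute
    their bound value as a point estimate and the result is exact but
    flagged ``censored_input``; otherwise the qualifier algebra decides
    the result qualifier.
    """
    if c_sediment.unit.dimension is not Dimension.SEDIMENT:
        raise ValueError(
            f"sediment concentration expected, got {c_sediment.unit.label}"
        )
    if c_water.unit.dimension is not Dimension.AQUEOUS:
        raise ValueError(f"water concentration expected, got {c_water.unit.label}")

    censored = c_sediment.is_censored or c_water.is_censored
    r = ratio(c_sediment, c_water)
    qualifier = Qualifier.EXACT if censored_as_point else r.qualifier
    return PartitionResult(
        site=site,
        compound=compound,
        kd_L_per_kg=r.value,
        qualifier=qualifier,
        c_sediment=c_sediment,
        c_water=c_water,
        toc_fraction=toc_fraction,
        censored_input=censored,
    )


def koc(result: PartitionResult) -> float:
    """Organic-carbon-normalised coefficient ``K_d / f_TOC``; the qualifier
    of the K_d carries over unchanged since f_TOC is an exact property."""
    if result.toc_fraction is None or not (0.0 < result.toc_fraction <= 1.0):
        raise MissingTocError(
            f"{result.site}/{result.compound}: TOC fraction must lie in "
            f"(0, 1], got {result.toc_fraction}"
        )
    return result.kd_L_per_kg / result.toc_fraction


def partition_results(
    measurements: list[Measurement],
    *,
    censored_as_point: bool = True,
) -> list[PartitionResult]:
    """Pair each sediment measurement with the surface-water measurement of
    the same site and compound.  Sites lacking either phase, non-detects
    without a reporting limit, and zero water concentrations are skipped."""
    water: dict[tuple[str, str], Measurement] = {}
    sediment: dict[tuple[str, str], Measurement] = {}
    for m in measurements:
        key = (m.site, m.compound)
        if m.matrix is Matrix.SURFACE_WATER:
            water[key] = m
        elif m.matrix is Matrix.SEDIMENT:
            sediment[key] = m
    out = []
    for key in sorted(sediment.keys() & water.keys()):
        sed, wat = sediment[key], water[key]
        if sed.quantity.value is None or wat.quantity.value is None:
            continue
        if wat.quantity.value <= 0:
            continue
        out.append(
            kd(
                sed.quantity,
                wat.quantity,
                site=key[0],
                compound=key[1],
                toc_fraction=sed.toc_fraction,
                censored_as_point=censored_as_point,
            )
        )
    return out


def partition_table(results: list[PartitionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        sed = r.c_sediment.canonical()
        wat = r.c_water.canonical()
        rows.append(
            {
                "site": r.site,
                "compound": r.compound,
                "c_sed_ng_kg": sed.value,
                "c_water_ng_L": wat.value,
                "kd_L_kg": r.kd_L_per_kg,
                "qualifier": r.qualifier.value,
                "toc_fraction": r.toc_fraction,
                "koc_L_kg": r.koc_L_per_kg,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "compound",
            "c_sed_ng_kg",
            "c_water_ng_L",
            "kd_L_kg",
            "qualifier",
            "toc_fraction",
            "koc_L_kg",
        ],
    )
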