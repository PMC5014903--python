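"""Domain records shared by every pipeline stage.

A :class:`Compound` is a physicochemical/pharmacological descriptor keyed by
name; :class:`SamplingSite` and :class:`Measurement` describe one analysis of
one matrix at one point of the catchment; :class:`ToxEndpoint` is a literature
ecotoxicity result from which a PNEC is derived; :class:`ConsumptionRecord`
is a regional drug-consumption statistic in defined daily doses (DDD).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .quantities import Dimension, Quantity


class ChargeClass(str, enum.Enum):
    """Dominant charge state at pH 7."""

    ACIDIC = "acidic"
    BASIC = "basic"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class Compound:
    """Physicochemical and excretion descriptor of one pharmaceutical.

    ``f_excreted_unchanged`` is the fraction of an ingested dose excreted as
    the parent compound.  Literature values frequently conflict, so it is
    stored as a (low, high) interval; the midpoint serves as the default
    point estimate.
    """

    name: str
    mw: float  # g/mol
    sw: float  # water solubility, mg/L
    logp: float  # octanol-water partition coefficient
    pka: float | None = None
    f_excreted_unchanged: tuple[float, float] | None = None
    charge_class: ChargeClass = ChargeClass.NEUTRAL

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.name}: molecular weight must be positive")
        if self.sw < 0:
            raise ValueError(f"{self.name}: water solubility must be >= 0")
        if self.f_excreted_unchanged is not None:
            low, high = self.f_excreted_unchanged
            if not (0.0 <= low <= high <= 1.0):
                raise ValueError(
                    f"{self.name}: excretion interval must satisfy "
                    f"0 <= low <= high <= 1, got ({low}, {high})"
                )

    @property
    def f_excreted_mid(self) -> float | None:
        if self.f_excreted_unchanged is None:
            return None
        low, high = self.f_excreted_unchanged
        return (low + high) / 2.0


class SiteKind(str, enum.Enum):
    RIVER = "river"
    LAKE = "lake"
    WWTP = "wwtp"
    LANDFILL = "landfill"
    CHANNEL = "channel"


@dataclass(frozen=True)
class SamplingSite:
    id: str
    kind: SiteKind
    description: str = ""


class Matrix(str, enum.Enum):
    INFLUENT = "influent"
    EFFLUENT = "effluent"
    SURFACE_WATER = "surface_water"
    LEACHATE = "leachate"
    SEDIMENT = "sediment"

    @property
    def dimension(self) -> Dimension:
        if self is Matrix.SEDIMENT:
            return Dimension.SEDIMENT
        return Dimension.AQUEOUS


class SampleType(str, enum.Enum):
    GRAB = "grab"
    COMPOSITE_24H = "composite_24h"


@dataclass(frozen=True)
class Measurement:
    """One sample of one compound at one site in one matrix.

    Aqueous matrices must use mass-per-volume units, sediment mass per dry
    mass; the sediment total-organic-carbon fraction travels with the
    sediment measurement because K_oc normalisation needs it.
    """

    site: str
    compound: str
    matrix: Matrix
    quantity: Quantity
    sample_type: SampleType = SampleType.GRAB
    toc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.quantity.unit.dimension is not self.matrix.dimension:
            raise ValueError(
                f"{self.site}/{self.compound}: {self.matrix.value} measurement "
                f"cannot use unit {self.quantity.unit.label}"
            )
        if self.toc_fraction is not None:
            if self.matrix is not Matrix.SEDIMENT:
                raise ValueError(
                    f"{self.site}/{self.compound}: toc_fraction only applies "
                    "to sediment measurements"
                )
            if not (0.0 <= self.toc_fraction <= 1.0):
                raise ValueError(
                    f"{self.site}/{self.compound}: toc_fraction must lie in "
                    f"[0, 1], got {self.toc_fraction}"
                )


class EndpointType(str, enum.Enum):
    NOEC = "NOEC"
    LOEC = "LOEC"


@dataclass(frozen=True)
class ToxEndpoint:
    """One literature ecotoxicity endpoint (aqueous exposure)."""

    compound: str
    species: str
    test: str
    endpoint_type: EndpointType
    value: Quantity
    source: str = ""

    def __post_init__(self) -> None:
        if self.value.unit.dimension is not Dimension.AQUEOUS:
            raise ValueError(
                f"{self.compound}: endpoint value must be an aqueous "
                f"concentration, got {self.value.unit.label}"
            )
        if self.value.value is None or self.value.value <= 0:
            raise ValueError(f"{self.compound}: endpoint value must be > 0")


@dataclass(frozen=True)
class ConsumptionRecord:
    """Regional consumption of one drug for one year, in DDD counts."""

    compound: str
    n_ddd: int
    ddd_mg: float
    region: str = ""
    year: int = 0
    population: int | None = None

    def __post_init__(self) -> None:
        if self.n_ddd < 0:
            raise ValueError(f"{self.compound}: n_ddd must be >= 0")
        if self.ddd_mg <= 0:
            raise ValueError(f"{self.compound}: ddd_mg must be > 0")
        if self.population is not None and self.population <= 0:
            raise ValueError(f"{self.compound}: population must be positive")
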