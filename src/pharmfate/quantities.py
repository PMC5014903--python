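"""Unit- and censoring-aware quantities.

Environmental monitoring tables mix units (ng/L for water, ng/kg dry weight
for sediment) and censoring qualifiers: values below a limit of detection are
reported as "<LOD", saturated or bounded values as ">x", and outright absences
as "not detected", sometimes without any reporting limit at all.  Every
statistic downstream of such a table (removal efficiency, distribution
coefficient, risk quotient) is a ratio, so censoring must propagate through
division with the correct bound direction.

:class:`Quantity` carries value, unit and qualifier together.  The module
provides the two primitives the whole pipeline is built from:

* :func:`convert` — exact decimal rescaling between compatible units;
* :func:`ratio` — division with a closed qualifier algebra (an exact value
  divided by an upper bound is a lower bound, two bounds in conflicting
  directions are indeterminate, ...).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace


class UnitError(ValueError):
    """Raised for unknown units or dimensionally incompatible operations."""


class CensoringError(ValueError):
    """Raised when arithmetic is attempted on a non-detect without a limit."""


class UndefinedRatioError(ValueError):
    """Raised when a ratio's denominator is zero or carries no information."""


class Dimension(enum.Enum):
    AQUEOUS = "aqueous concentration"
    SEDIMENT = "sediment concentration (dry weight)"
    MASS = "mass"


class Unit(enum.Enum):
    """Supported units; the second field is the decimal exponent relative to
    the canonical unit of the dimension (ng/L, ng/kg dw, kg)."""

    NG_PER_L = ("ng/L", Dimension.AQUEOUS, 0)
    UG_PER_L = ("ug/L", Dimension.AQUEOUS, 3)
    MG_PER_L = ("mg/L", Dimension.AQUEOUS, 6)
    NG_PER_KG = ("ng/kg", Dimension.SEDIMENT, 0)
    UG_PER_KG = ("ug/kg", Dimension.SEDIMENT, 3)
    MG_PER_KG = ("mg/kg", Dimension.SEDIMENT, 6)
    KG = ("kg", Dimension.MASS, 0)
    MG = ("mg", Dimension.MASS, -6)

    def __init__(self, label: str, dimension: Dimension, exponent: int):
        self.label = label
        self.dimension = dimension
        self.exponent = exponent

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    @classmethod
    def parse(cls, text: str) -> "Unit":
        """Parse a unit token.  Accepts ``µ`` or ``u``, an optional ``_dw``
        dry-weight suffix on sediment units, and is case-insensitive in the
        prefix (``ng/L`` == ``NG/l``)."""
        token = text.strip().replace("µ", "u").replace("μ", "u")
        token = re.sub(r"_?dw$", "", token, flags=re.IGNORECASE)
        token = token.lower().rstrip("_")
        for unit in cls:
            if unit.label.lower() == token:
                return unit
        raise UnitError(f"unknown unit: {text!r}")


#: canonical unit per dimension (exponent 0)
CANONICAL = {
    Dimension.AQUEOUS: Unit.NG_PER_L,
    Dimension.SEDIMENT: Unit.NG_PER_KG,
    Dimension.MASS: Unit.KG,
}


class Qualifier(str, enum.Enum):
    EXACT = "exact"
    LESS_THAN = "less_than"
    GREATER_THAN = "greater_than"
    AT_MOST = "at_most"
    AT_LEAST = "at_least"
    NOT_DETECTED = "not_detected"
    #: result-only state: censored inputs bounded in conflicting directions
    INDETERMINATE = "indeterminate"


#: bound direction: -1 the value is an upper bound, +1 a lower bound, 0 exact
_DIRECTION = {
    Qualifier.EXACT: 0,
    Qualifier.LESS_THAN: -1,
    Qualifier.AT_MOST: -1,
    Qualifier.GREATER_THAN: +1,
    Qualifier.AT_LEAST: +1,
}

_STRICT = {Qualifier.LESS_THAN, Qualifier.GREATER_THAN}

_QUALIFIER_SYMBOL = {
    Qualifier.EXACT: "",
    Qualifier.LESS_THAN: "<",
    Qualifier.GREATER_THAN: ">",
    Qualifier.AT_MOST: "≤",
    Qualifier.AT_LEAST: "≥",
    Qualifier.NOT_DETECTED: "nd",
    Qualifier.INDETERMINATE: "?",
}


@dataclass(frozen=True)
class Quantity:
    """A non-negative measured value with unit and censoring qualifier.

    ``not_detected`` may carry the reporting limit as its value; when the
    limit is unknown ``value`` is ``None`` and all arithmetic refuses the
    quantity rather than silently substituting zero.
    """

    value: float | None
    unit: Unit
    qualifier: Qualifier = Qualifier.EXACT

    def __post_init__(self) -> None:
        if self.value is None:
            if self.qualifier is not Qualifier.NOT_DETECTED:
                raise ValueError(
                    "only not_detected quantities may omit the value"
                )
        elif self.value < 0:
            raise ValueError(f"negative quantity value: {self.value}")

    # -- convenience ----------------------------------------------------
    @property
    def is_censored(self) -> bool:
        return self.qualifier is not Qualifier.EXACT

    def arithmetic_qualifier(self) -> Qualifier:
        """The qualifier used in arithmetic: a non-detect with a reporting
        limit behaves as ``less_than(limit)``; without one it refuses."""
        q = self.qualifier
        if q is Qualifier.NOT_DETECTED:
            if self.value is None:
                raise CensoringError(
                    "not_detected without a reporting limit cannot enter "
                    "arithmetic"
                )
            return Qualifier.LESS_THAN
        if q is Qualifier.INDETERMINATE:
            raise CensoringError("indeterminate quantities cannot enter arithmetic")
        return q

    def canonical(self) -> "Quantity":
        return convert(self, CANONICAL[self.unit.dimension])

    def __str__(self) -> str:
        sym = _QUALIFIER_SYMBOL[self.qualifier]
        if self.value is None:
            return f"nd [{self.unit.label}]"
        return f"{sym}{self.value:g} {self.unit.label}"


def convert(q: Quantity, target: Unit) -> Quantity:
    """Rescale ``q`` to ``target`` by an exact power of ten.

    Conversion factors are powers of ten applied as exact integer
    multiplication or division, so round trips are lossless whenever the
    original value is representable.
    """
    if q.unit.dimension is not target.dimension:
        raise UnitError(
            f"cannot convert {q.unit.label} ({q.unit.dimension.value}) to "
            f"{target.label} ({target.dimension.value})"
        )
    if q.value is None:
        return replace(q, unit=target)
    diff = q.unit.exponent - target.exponent
    if diff >= 0:
        value = q.value * 10**diff
    else:
        value = q.value / 10**-diff
    return replace(q, value=value, unit=target)


@dataclass(frozen=True)
class Ratio:
    """A quotient of two quantities: dimensionless or a derived unit such as
    L/kg, with the qualifier from the censoring algebra."""

    value: float
    qualifier: Qualifier
    unit: str = ""
    warning: str | None = None

    def __str__(self) -> str:
        sym = _QUALIFIER_SYMBOL[self.qualifier]
        suffix = f" {self.unit}" if self.unit else ""
        return f"{sym}{self.value:g}{suffix}"


#: dimensions that admit a defined quotient, and its unit label
_QUOTIENT_UNIT = {
    (Dimension.AQUEOUS, Dimension.AQUEOUS): "",
    (Dimension.SEDIMENT, Dimension.SEDIMENT): "",
    (Dimension.MASS, Dimension.MASS): "",
    (Dimension.SEDIMENT, Dimension.AQUEOUS): "L/kg",
    (Dimension.AQUEOUS, Dimension.SEDIMENT): "kg/L",
}


def combine_qualifiers(num: Qualifier, den: Qualifier) -> Qualifier:
    """Qualifier of ``num/den`` under interval semantics.

    The numerator contributes its own bound direction, the denominator the
    inverse of its direction; agreeing contributions keep the direction,
    conflicting ones yield ``indeterminate``.  Strict bounds stay strict
    whenever any contributing bound is strict.
    """
    d_num = _DIRECTION[num]
    d_den = -_DIRECTION[den]
    if d_num == 0 and d_den == 0:
        return Qualifier.EXACT
    if d_num != 0 and d_den != 0 and d_num != d_den:
        return Qualifier.INDETERMINATE
    direction = d_num if d_num != 0 else d_den
    strict = num in _STRICT or den in _STRICT
    if direction < 0:
        return Qualifier.LESS_THAN if strict else Qualifier.AT_MOST
    return Qualifier.GREATER_THAN if strict else Qualifier.AT_LEAST


def ratio(numerator: Quantity, denominator: Quantity) -> Ratio:
    """Divide two quantities, propagating units and censoring.

    Raises :class:`UndefinedRatioError` for a zero denominator,
    :class:`CensoringError` when either side is a non-detect without a
    reporting limit, and :class:`UnitError` for dimensions with no defined
    quotient.
    """
    key = (numerator.unit.dimension, denominator.unit.dimension)
    if key not in _QUOTIENT_UNIT:
        raise UnitError(
            f"no defined quotient for {numerator.unit.label} / "
            f"{denominator.unit.label}"
        )
    q_num = numerator.arithmetic_qualifier()
    q_den = denominator.arithmetic_qualifier()
    num = numerator.canonical()
    den = denominator.canonical()
    if den.value is None or num.value is None:  # pragma: no cover - guarded above
        raise CensoringError("missing value")
    if den.value <= 0:
        raise UndefinedRatioError("ratio denominator must be positive")
    qualifier = combine_qualifiers(q_num, q_den)
    warning = None
    if qualifier is Qualifier.INDETERMINATE:
        warning = (
            f"censored in conflicting directions: {q_num.value} / {q_den.value}"
        )
    return Ratio(
        value=num.value / den.value,
        qualifier=qualifier,
        unit=_QUOTIENT_UNIT[key],
        warning=warning,
    )


_QUALIFIER_PREFIX = {
    "<": Qualifier.LESS_THAN,
    ">": Qualifier.GREATER_THAN,
    "≤": Qualifier.AT_MOST,
    "≥": Qualifier.AT_LEAST,
    "<=": Qualifier.AT_MOST,
    ">=": Qualifier.AT_LEAST,
}


def parse_number(text: str, decimal_comma: bool = False) -> float:
    """Parse a numeric token, optionally under the European convention where
    ``.`` groups thousands and ``,`` is the decimal separator (so ``11.000``
    reads as 11000).  The convention is an explicit flag, never guessed."""
    token = text.strip()
    if decimal_comma:
        token = token.replace(".", "").replace(",", ".")
    else:
        token = token.replace(",", "")
    return float(token)


def parse_quantity(text: str, unit: Unit | str, decimal_comma: bool = False) -> Quantity:
    """Parse values like ``"331"``, ``">8000"``, ``"≤12"`` or ``"nd"``."""
    if isinstance(unit, str):
        unit = Unit.parse(unit)
    token = text.strip()
    if token.lower() in {"nd", "n.d.", "not_detected", "not detected"}:
        return Quantity(None, unit, Qualifier.NOT_DETECTED)
    for prefix in ("<=", ">=", "<", ">", "≤", "≥"):
        if token.startswith(prefix):
            value = parse_number(token[len(prefix):], decimal_comma)
            return Quantity(value, unit, _QUALIFIER_PREFIX[prefix])
    return Quantity(parse_number(token, decimal_comma), unit)
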