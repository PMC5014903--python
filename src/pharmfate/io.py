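"""CSV/YAML readers and writers with strict row-level validation.

All tables are comma-separated UTF-8 with a header row and "." as decimal
separator; a ``decimal_comma`` flag switches the value columns to the
European convention ("." groups thousands, "," is the decimal mark) for
exported tables written that way.  Validation collects every row error with
its line number before raising, so a malformed file is reported once and
completely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .quantities import Qualifier, Quantity, Unit, parse_number, parse_quantity
from .records import (
    ChargeClass,
    Compound,
    ConsumptionRecord,
    EndpointType,
    Matrix,
    Measurement,
    SampleType,
    SamplingSite,
    SiteKind,
    ToxEndpoint,
)

log = logging.getLogger("pharmfate")


class TableValidationError(ValueError):
    """One or more rows failed validation; ``errors`` is a list of
    (file, line_number, message) tuples covering every failure."""

    def __init__(self, errors: list[tuple[str, int, str]]):
        self.errors = errors
        lines = "\n".join(f"  {f}:{n}: {msg}" for f, n, msg in errors)
        super().__init__(f"{len(errors)} validation error(s):\n{lines}")


def _read_rows(path: str | Path, required: list[str]) -> tuple[pd.DataFrame, str]:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableValidationError(
            [(path.name, 1, f"missing required column(s): {', '.join(missing)}")]
        )
    return frame, path.name


def _collect(errors, fname, line, exc_or_msg):
    errors.append((fname, line, str(exc_or_msg)))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_compounds(path: str | Path) -> dict[str, Compound]:
    frame, fname = _read_rows(
        path, ["name", "mw_g_mol", "sw_mg_L", "logp", "charge_class"]
    )
    errors: list[tuple[str, int, str]] = []
    out: dict[str, Compound] = {}
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            low = row.get("f_excreted_low", "")
            high = row.get("f_excreted_high", "")
            interval = None
            if low != "" or high != "":
                interval = (float(low), float(high if high != "" else low))
            compound = Compound(
                name=row["name"],
                mw=float(row["mw_g_mol"]),
                sw=float(row["sw_mg_L"]),
                logp=float(row["logp"]),
                pka=float(row["pka"]) if row.get("pka", "") != "" else None,
                f_excreted_unchanged=interval,
                charge_class=ChargeClass(row["charge_class"]),
            )
            if compound.name in out:
                raise ValueError(f"duplicate compound {compound.name!r}")
            out[compound.name] = compound
        except (ValueError, KeyError) as exc:
            _collect(errors, fname, line, exc)
    if errors:
        raise TableValidationError(errors)
    return out


def read_sites(path: str | Path) -> dict[str, SamplingSite]:
    frame, fname = _read_rows(path, ["id", "kind"])
    errors: list[tuple[str, int, str]] = []
    out: dict[str, SamplingSite] = {}
    for i, row in frame.iterrows():
        line = i + 2
        try:
            site = SamplingSite(
                id=row["id"],
                kind=SiteKind(row["kind"]),
                description=row.get("description", ""),
            )
            if site.id in out:
                raise ValueError(f"duplicate site id {site.id!r}")
            out[site.id] = site
        except ValueError as exc:
            _collect(errors, fname, line, exc)
    if errors:
        raise TableValidationError(errors)
    return out


def read_measurements(
    path: str | Path,
    sites: dict[str, SamplingSite] | None = None,
    compounds: dict[str, Compound] | None = None,
    decimal_comma: bool = False,
) -> list[Measurement]:
    """Read measurements.csv; with registries given, site and compound
    references are checked (influent/effluent may only sit at WWTP sites)."""
    frame, fname = _read_rows(
        path, ["site", "compound", "matrix", "value", "qualifier", "unit"]
    )
    errors: list[tuple[str, int, str]] = []
    out: list[Measurement] = []
    for i, row in frame.iterrows():
        line = i + 2
        try:
            qualifier_text = row["qualifier"].strip()
            qualifier = (
                Qualifier.EXACT if qualifier_text == "" else Qualifier(qualifier_text)
            )
            value_text = row["value"].strip()
            if value_text == "":
                if qualifier is not Qualifier.NOT_DETECTED:
                    raise ValueError("empty value requires qualifier not_detected")
                quantity = Quantity(None, Unit.parse(row["unit"]), qualifier)
            else:
                quantity = Quantity(
                    parse_number(value_text, decimal_comma),
                    Unit.parse(row["unit"]),
                    qualifier,
                )
            toc_text = row.get("toc_fraction", "").strip()
            matrix = Matrix(row["matrix"])
            sample_text = row.get("sample_type", "").strip()
            m = Measurement(
                site=row["site"],
                compound=row["compound"],
                matrix=matrix,
                quantity=quantity,
                sample_type=(
                    SampleType.GRAB if sample_text == "" else SampleType(sample_text)
                ),
                toc_fraction=float(toc_text) if toc_text != "" else None,
            )
            if sites is not None:
                if m.site not in sites:
                    raise ValueError(f"unknown site {m.site!r}")
                if (
                    m.matrix in (Matrix.INFLUENT, Matrix.EFFLUENT)
                    and sites[m.site].kind is not SiteKind.WWTP
                ):
                    raise ValueError(
                        f"{m.matrix.value} measurement at non-WWTP site {m.site!r}"
                    )
            if compounds is not None and m.compound not in compounds:
                raise ValueError(f"unknown compound {m.compound!r}")
            out.append(m)
        except ValueError as exc:
            _collect(errors, fname, line, exc)
    if errors:
        raise TableValidationError(errors)
    return out


def read_consumption(
    path: str | Path, compounds: dict[str, Compound] | None = None
) -> list[ConsumptionRecord]:
    frame, fname = _read_rows(path, ["compound", "n_ddd", "ddd_mg"])
    errors: list[tuple[str, int, str]] = []
    out: list[ConsumptionRecord] = []
    for i, row in frame.iterrows():
        line = i + 2
        try:
            pop = row.get("population", "").strip()
            rec = ConsumptionRecord(
                compound=row["compound"],
                n_ddd=int(float(row["n_ddd"])),
                ddd_mg=float(row["ddd_mg"]),
                region=row.get("region", ""),
                year=int(row["year"]) if row.get("year", "").strip() else 0,
                population=int(float(pop)) if pop else None,
            )
            if compounds is not None and rec.compound not in compounds:
                raise ValueError(f"unknown compound {rec.compound!r}")
            out.append(rec)
        except ValueError as exc:
            _collect(errors, fname, line, exc)
    if errors:
        raise TableValidationError(errors)
    return out


def read_endpoints(
    path: str | Path, compounds: dict[str, Compound] | None = None
) -> list[ToxEndpoint]:
    frame, fname = _read_rows(
        path, ["compound", "species", "endpoint_type", "value", "unit"]
    )
    errors: list[tuple[str, int, str]] = []
    out: list[ToxEndpoint] = []
    for i, row in frame.iterrows():
        line = i + 2
        try:
            endpoint = ToxEndpoint(
                compound=row["compound"],
                species=row["species"],
                test=row.get("test", ""),
                endpoint_type=EndpointType(row["endpoint_type"]),
                value=parse_quantity(row["value"], row["unit"]),
                source=row.get("source", ""),
            )
            if compounds is not None and endpoint.compound not in compounds:
                raise ValueError(f"unknown compound {endpoint.compound!r}")
            out.append(endpoint)
        except ValueError as exc:
            _collect(errors, fname, line, exc)
    if errors:
        raise TableValidationError(errors)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_compounds(compounds: list[Compound], path: str | Path) -> None:
    rows = []
    for c in compounds:
        low, high = (
            c.f_excreted_unchanged if c.f_excreted_unchanged else (None, None)
        )
        rows.append(
            {
                "name": c.name,
                "mw_g_mol": c.mw,
                "pka": c.pka,
                "sw_mg_L": c.sw,
                "logp": c.logp,
                "f_excreted_low": low,
                "f_excreted_high": high,
                "charge_class": c.charge_class.value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sites(sites: list[SamplingSite], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": s.id, "kind": s.kind.value, "description": s.description}
         for s in sites]
    ).to_csv(path, index=False)


def measurements_frame(measurements: list[Measurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        q = m.quantity
        rows.append(
            {
                "site": m.site,
                "compound": m.compound,
                "matrix": m.matrix.value,
                "value": "" if q.value is None else repr(q.value),
                "qualifier": "" if q.qualifier is Qualifier.EXACT else q.qualifier.value,
                "unit": q.unit.label,
                "sample_type": m.sample_type.value,
                "toc_fraction": "" if m.toc_fraction is None else m.toc_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site", "compound", "matrix", "value", "qualifier", "unit",
                 "sample_type", "toc_fraction"],
    )


def write_measurements(measurements: list[Measurement], path: str | Path) -> None:
    measurements_frame(measurements).to_csv(path, index=False)


def write_consumption(records: list[ConsumptionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound": r.compound,
                "n_ddd": r.n_ddd,
                "ddd_mg": r.ddd_mg,
                "region": r.region,
                "year": r.year,
                "population": "" if r.population is None else r.population,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_endpoints(endpoints: list[ToxEndpoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound": e.compound,
                "species": e.species,
                "test": e.test,
                "endpoint_type": e.endpoint_type.value,
                "value": e.value.value,
                "unit": e.value.unit.label,
                "source": e.source,
            }
            for e in endpoints
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Every silently-applied default matters scientifically, so all of them
    are recorded verbatim into the report header and logged once per run.
    """

    compounds: Path
    sites: Path
    measurements: Path
    consumption: Path | None = None
    endpoints: Path | None = None
    censored_as_point: bool = True
    wastewater_L_per_capita_day: float = 200.0
    region_population: int = 1_250_000
    population_served: dict[str, int] = field(default_factory=dict)
    risk_site: str = "SP7"
    significant_figures: int = 4
    decimal_comma: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("compounds", "sites", "measurements", "consumption",
                     "endpoints"):
            value = getattr(self, name)
            if value is not None:
                path = Path(value)
                if not path.exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
                setattr(self, name, path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        for key in ("compounds", "sites", "measurements", "consumption",
                    "endpoints"):
            if raw.get(key) is not None:
                raw[key] = base / raw[key]
        return cls(**raw)


@dataclass
class Registries:
    compounds: dict[str, Compound]
    sites: dict[str, SamplingSite]
    measurements: list[Measurement]
    consumption: list[ConsumptionRecord]
    endpoints: list[ToxEndpoint]


def load_tables(config: RunConfig) -> Registries:
    """Load and cross-validate every input table; row errors from all files
    are collected and raised together."""
    errors: list[tuple[str, int, str]] = []
    compounds: dict[str, Compound] = {}
    sites: dict[str, SamplingSite] = {}
    measurements: list[Measurement] = []
    consumption: list[ConsumptionRecord] = []
    endpoints: list[ToxEndpoint] = []

    def guarded(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except TableValidationError as exc:
            errors.extend(exc.errors)
            return None

    compounds = guarded(read_compounds, config.compounds) or {}
    sites = guarded(read_sites, config.sites) or {}
    measurements = guarded(
        read_measurements, config.measurements, sites, compounds,
        config.decimal_comma,
    ) or []
    if config.consumption is not None:
        consumption = guarded(read_consumption, config.consumption, compounds) or []
    if config.endpoints is not None:
        endpoints = guarded(read_endpoints, config.endpoints, compounds) or []
    if errors:
        raise TableValidationError(errors)
    log.info(
        "loaded %d compounds, %d sites, %d measurements, %d consumption "
        "records, %d endpoints",
        len(compounds), len(sites), len(measurements), len(consumption),
        len(endpoints),
    )
    return Registries(compounds, sites, measurements, consumption, endpoints)
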