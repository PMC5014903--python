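"""Synthetic catchment generator and parameter-recovery harness.

A steady-state, single-time-point surface-water network: an ordered list of
nodes (river source, treatment plants, landfill, channel, lake, junctions)
connected as a directed acyclic path with side inflows.  Per compound, the
generator knows the true influent concentration, treatment removal,
sediment-water distribution coefficient and leachate concentration, and
propagates water concentrations downstream:

* WWTP:        C_effluent = C_influent x (1 - removal/100)
* junction:    C = sum(Q_i C_i) / sum(Q_i), optional extra clean dilution
* sediment:    C_sed = K_d x C_water x (f_TOC / f_TOC_reference)

Sorption is represented as an equilibrium observation, not a sink, so water
concentrations only change through explicit removal and dilution.  Every
emitted measurement is multiplied by lognormal noise exp(sigma Z) and then
left-censored against a limit of detection.  Generation is fully
deterministic given the spec and one integer seed.

:func:`recover` closes the loop: it runs the removal and partitioning
estimators on the simulated measurements and reports estimate minus truth,
which is how estimator bias and censoring behaviour are quantified.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as GENERATOR_VERSION
from .partitioning import PartitionResult, partition_results
from .quantities import Qualifier, Quantity, Unit
from .records import Matrix, Measurement, SampleType, SamplingSite, SiteKind
from .removal import (
    RemovalResult,
    UndefinedRemovalError,
    pairs_from_measurements,
    removal_efficiency,
)


class CatchmentSpecError(ValueError):
    """Invalid network topology (cycle, forward reference, bad flows)."""


class NodeKind(str, enum.Enum):
    RIVER_SOURCE = "river_source"
    WWTP = "wwtp"
    LANDFILL = "landfill"
    CHANNEL = "channel"
    LAKE = "lake"
    JUNCTION = "junction"


_SITE_KIND = {
    NodeKind.RIVER_SOURCE: SiteKind.RIVER,
    NodeKind.WWTP: SiteKind.WWTP,
    NodeKind.LANDFILL: SiteKind.LANDFILL,
    NodeKind.CHANNEL: SiteKind.CHANNEL,
    NodeKind.LAKE: SiteKind.LAKE,
    NodeKind.JUNCTION: SiteKind.RIVER,
}


@dataclass(frozen=True)
class NodeSpec:
    """One node of the catchment.

    ``upstream`` lists ids of earlier nodes whose outflow feeds this node;
    sources (river, WWTP, landfill) leave it empty.  ``dilution_factor`` >= 1
    models unmeasured clean inflow at receiving nodes: the mixed
    concentration is divided by it (and the outflow multiplied by it, so
    contaminant mass is conserved).  ``toc_fraction`` set on a node makes it
    emit a sediment measurement."""

    id: str
    kind: NodeKind
    flow: float = 1.0
    upstream: tuple[str, ...] = ()
    dilution_factor: float = 1.0
    toc_fraction: float | None = None
    sample_types: tuple[SampleType, ...] = (SampleType.GRAB,)
    source_ng_L: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.flow <= 0:
            raise CatchmentSpecError(f"{self.id}: flow must be positive")
        if self.dilution_factor < 1.0:
            raise CatchmentSpecError(
                f"{self.id}: dilution_factor must be >= 1"
            )


@dataclass(frozen=True)
class CompoundTruth:
    """True fate parameters of one compound.

    ``influent_ng_L`` and ``removal_percent`` may be scalars (shared by all
    plants) or mappings ``{plant_id: value}`` whose values may themselves be
    ``{sample_type: value}`` mappings."""

    name: str
    influent_ng_L: float | dict = 0.0
    removal_percent: float | dict = 0.0
    kd_L_kg: float = 0.0
    leachate_ng_L: float = 0.0

    def influent_at(self, plant: str, sample_type: SampleType) -> float:
        return _lookup(self.influent_ng_L, plant, sample_type)

    def removal_at(self, plant: str, sample_type: SampleType) -> float:
        return _lookup(self.removal_percent, plant, sample_type)


def _lookup(value, plant: str, sample_type: SampleType) -> float:
    if isinstance(value, dict):
        value = value[plant]
    if isinstance(value, dict):
        value = value[sample_type.value if not isinstance(sample_type, str) else sample_type]
    return float(value)


@dataclass(frozen=True)
class CatchmentSpec:
    nodes: tuple[NodeSpec, ...]
    compounds: tuple[CompoundTruth, ...]
    noise_sigma: float = 0.1
    lod_ng_L: float = 1.0
    lod_ng_kg: float = 100.0
    reference_toc: float = 0.079
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for node in self.nodes:
            if node.id in seen:
                raise CatchmentSpecError(f"duplicate node id {node.id!r}")
            for up in node.upstream:
                if up not in seen:
                    raise CatchmentSpecError(
                        f"{node.id}: upstream reference {up!r} is undefined "
                        "or later in the list (the node order must be a "
                        "topological order; cycles are impossible under it)"
                    )
            seen.add(node.id)

    def sites(self) -> list[SamplingSite]:
        return [
            SamplingSite(n.id, _SITE_KIND[n.kind], n.description or n.kind.value)
            for n in self.nodes
        ]


@dataclass(frozen=True)
class SimulatedDataset:
    measurements: tuple[Measurement, ...]
    truth: CatchmentSpec
    seed: int
    generator_version: str = GENERATOR_VERSION

    def measurements_frame(self) -> pd.DataFrame:
        from .io import measurements_frame

        return measurements_frame(list(self.measurements))

    def to_dir(self, path: str | Path) -> None:
        """Write sites.csv, measurements.csv and truth.json; byte-identical
        for identical spec and seed."""
        from .io import write_measurements, write_sites

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_sites(self.truth.sites(), path / "sites.csv")
        write_measurements(list(self.measurements), path / "measurements.csv")
        truth = {
            "seed": self.seed,
            "generator_version": self.generator_version,
            "note": (
                "synthetic catchment; flows and source levels are invented "
                "scenario parameters, not field observations"
            ),
            "spec": _spec_dict(self.truth),
        }
        (path / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )


def _spec_dict(spec: CatchmentSpec) -> dict:
    d = asdict(spec)
    for node in d["nodes"]:
        node["kind"] = node["kind"].value if hasattr(node["kind"], "value") else node["kind"]
        node["upstream"] = list(node["upstream"])
        node["sample_types"] = [
            s.value if hasattr(s, "value") else s for s in node["sample_types"]
        ]
    d["nodes"] = list(d["nodes"])
    d["compounds"] = list(d["compounds"])
    return d


def spec_from_yaml(path: str | Path) -> CatchmentSpec:
    """Load a CatchmentSpec from YAML (same structure as truth.json's
    ``spec`` block)."""
    raw = yaml.safe_load(Path(path).read_text())
    nodes = tuple(
        NodeSpec(
            id=n["id"],
            kind=NodeKind(n["kind"]),
            flow=float(n.get("flow", 1.0)),
            upstream=tuple(n.get("upstream", ())),
            dilution_factor=float(n.get("dilution_factor", 1.0)),
            toc_fraction=n.get("toc_fraction"),
            sample_types=tuple(
                SampleType(s) for s in n.get("sample_types", ["grab"])
            ),
            source_ng_L=float(n.get("source_ng_L", 0.0)),
            description=n.get("description", ""),
        )
        for n in raw["nodes"]
    )
    compounds = tuple(
        CompoundTruth(
            name=c["name"],
            influent_ng_L=c.get("influent_ng_L", 0.0),
            removal_percent=c.get("removal_percent", 0.0),
            kd_L_kg=float(c.get("kd_L_kg", 0.0)),
            leachate_ng_L=float(c.get("leachate_ng_L", 0.0)),
        )
        for c in raw["compounds"]
    )
    return CatchmentSpec(
        nodes=nodes,
        compounds=compounds,
        noise_sigma=float(raw.get("noise_sigma", 0.1)),
        lod_ng_L=float(raw.get("lod_ng_L", 1.0)),
        lod_ng_kg=float(raw.get("lod_ng_kg", 100.0)),
        reference_toc=float(raw.get("reference_toc", 0.079)),
        seed=int(raw.get("seed", 0)),
    )


def simulate(spec: CatchmentSpec, seed: int | None = None) -> SimulatedDataset:
    """Generate one noisy, censored measurement set from a catchment spec.

    Nodes are processed in list order and compounds in spec order, so the
    random-number stream (one numpy Generator seeded once) is reproducible.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sigma = spec.noise_sigma

    def noisy(value: float) -> float:
        # one draw per emitted measurement, also at sigma=0, so that the
        # measurement count does not change the stream alignment
        z = rng.standard_normal()
        return value * float(np.exp(sigma * z)) if sigma > 0 else value

    def emit_water(
        node_id: str,
        compound: str,
        matrix: Matrix,
        value: float,
        sample_type: SampleType = SampleType.GRAB,
    ) -> Measurement:
        v = noisy(value)
        if v < spec.lod_ng_L:
            q = Quantity(spec.lod_ng_L, Unit.NG_PER_L, Qualifier.LESS_THAN)
        else:
            q = Quantity(v, Unit.NG_PER_L)
        return Measurement(node_id, compound, matrix, q, sample_type)

    def emit_sediment(
        node_id: str, compound: str, value: float, toc: float
    ) -> Measurement:
        v = noisy(value)
        if v < spec.lod_ng_kg:
            q = Quantity(spec.lod_ng_kg, Unit.NG_PER_KG, Qualifier.LESS_THAN)
        else:
            q = Quantity(v, Unit.NG_PER_KG)
        return Measurement(
            node_id, compound, Matrix.SEDIMENT, q, SampleType.GRAB, toc
        )

    measurements: list[Measurement] = []
    # per node: (outflow, {compound: concentration ng/L}), noise-free truth
    outflow: dict[str, tuple[float, dict[str, float]]] = {}

    for node in spec.nodes:
        conc: dict[str, float] = {}
        flow = node.flow
        if node.kind is NodeKind.RIVER_SOURCE:
            conc = {c.name: node.source_ng_L for c in spec.compounds}
            for c in spec.compounds:
                measurements.append(
                    emit_water(node.id, c.name, Matrix.SURFACE_WATER, conc[c.name])
                )
        elif node.kind is NodeKind.LANDFILL:
            conc = {c.name: c.leachate_ng_L for c in spec.compounds}
            for c in spec.compounds:
                measurements.append(
                    emit_water(node.id, c.name, Matrix.LEACHATE, conc[c.name])
                )
        elif node.kind is NodeKind.WWTP:
            primary = node.sample_types[0]
            for st in node.sample_types:
                for c in spec.compounds:
                    influent = c.influent_at(node.id, st)
                    # (100 - r)/100 keeps round percentages exact in float
                    effluent = influent * (100.0 - c.removal_at(node.id, st)) / 100.0
                    measurements.append(
                        emit_water(node.id, c.name, Matrix.INFLUENT, influent, st)
                    )
                    measurements.append(
                        emit_water(node.id, c.name, Matrix.EFFLUENT, effluent, st)
                    )
                    if st is primary:
                        conc[c.name] = effluent
        else:  # channel, lake, junction: mix upstream flows
            q_in = sum(outflow[u][0] for u in node.upstream)
            if q_in <= 0:
                raise CatchmentSpecError(f"{node.id}: no upstream inflow")
            for c in spec.compounds:
                mass = sum(
                    outflow[u][0] * outflow[u][1][c.name] for u in node.upstream
                )
                conc[c.name] = mass / q_in / node.dilution_factor
            flow = q_in * node.dilution_factor
            if node.kind is not NodeKind.JUNCTION:
                for c in spec.compounds:
                    measurements.append(
                        emit_water(
                            node.id, c.name, Matrix.SURFACE_WATER, conc[c.name]
                        )
                    )
                if node.toc_fraction is not None:
                    toc_scaling = node.toc_fraction / spec.reference_toc
                    for c in spec.compounds:
                        c_sed = c.kd_L_kg * conc[c.name] * toc_scaling
                        measurements.append(
                            emit_sediment(
                                node.id, c.name, c_sed, node.toc_fraction
                            )
                        )
        outflow[node.id] = (flow, conc)

    return SimulatedDataset(
        measurements=tuple(measurements), truth=spec, seed=seed
    )


def steady_state(spec: CatchmentSpec) -> dict[str, dict[str, float]]:
    """Noise-free water concentrations per node (the propagation truth the
    measurements are drawn around); useful for mass-balance checks."""
    noiseless = CatchmentSpec(
        nodes=spec.nodes,
        compounds=spec.compounds,
        noise_sigma=0.0,
        lod_ng_L=0.0,
        lod_ng_kg=0.0,
        reference_toc=spec.reference_toc,
        seed=spec.seed,
    )
    ds = simulate(noiseless)
    out: dict[str, dict[str, float]] = {}
    for m in ds.measurements:
        if m.matrix in (Matrix.SURFACE_WATER, Matrix.EFFLUENT):
            # keep the first (primary sample-type) effluent per site/compound
            out.setdefault(m.site, {}).setdefault(
                m.compound, m.quantity.value or 0.0
            )
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemovalRecovery:
    plant: str
    compound: str
    sample_type: SampleType
    estimate: float | None
    truth: float
    error: float | None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class KdRecovery:
    site: str
    compound: str
    estimate: float | None
    truth: float
    error: float | None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RecoveryResult:
    removal: tuple[RemovalRecovery, ...]
    kd: tuple[KdRecovery, ...]

    def removal_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.removal])

    def kd_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.kd])


def recover(dataset: SimulatedDataset) -> RecoveryResult:
    """Run the removal and partitioning estimators on simulated data and
    report estimate - truth per compound.

    Censored or indeterminate estimates keep their flags and a ``None``
    error rather than pretending to be exact numbers; missing matrices
    simply yield no record for that plant/site (partial results carry on).
    """
    spec = dataset.truth
    truths = {c.name: c for c in spec.compounds}
    measurements = list(dataset.measurements)

    removal_records: list[RemovalRecovery] = []
    for pair in pairs_from_measurements(measurements):
        truth = truths[pair.compound].removal_at(pair.plant, pair.sample_type)
        flags: tuple[str, ...] = ()
        try:
            res = removal_efficiency(pair)
        except UndefinedRemovalError:
            removal_records.append(
                RemovalRecovery(
                    pair.plant, pair.compound, pair.sample_type,
                    None, truth, None, ("undefined",),
                )
            )
            continue
        flags = tuple(sorted(f.value for f in res.flags))
        exact = res.qualifier is Qualifier.EXACT
        removal_records.append(
            RemovalRecovery(
                pair.plant,
                pair.compound,
                pair.sample_type,
                res.efficiency_percent if exact else None,
                truth,
                res.efficiency_percent - truth if exact else None,
                flags,
            )
        )

    kd_records: list[KdRecovery] = []
    for res in partition_results(measurements, censored_as_point=False):
        truth = truths[res.compound].kd_L_kg
        exact = res.qualifier is Qualifier.EXACT
        flags = ("censored",) if res.censored_input else ()
        if res.qualifier is Qualifier.INDETERMINATE:
            flags = flags + ("indeterminate",)
        # undo the generator's TOC scaling so the estimate targets the true
        # coefficient also at nodes away from the reference TOC
        estimate = res.kd_L_per_kg
        if res.toc_fraction is not None and spec.reference_toc > 0:
            estimate /= res.toc_fraction / spec.reference_toc
        kd_records.append(
            KdRecovery(
                res.site,
                res.compound,
                estimate if exact else None,
                truth,
                estimate - truth if exact else None,
                flags,
            )
        )

    return RecoveryResult(tuple(removal_records), tuple(kd_records))


def simple_catchment(
    *,
    removal_percent: float = 50.0,
    kd_L_kg: float = 100.0,
    influent_ng_L: float = 1000.0,
    noise_sigma: float = 0.1,
    seed: int = 0,
    lod_ng_L: float = 0.0,
    lod_ng_kg: float = 0.0,
) -> CatchmentSpec:
    """Minimal one-plant, one-channel network used by recovery studies."""
    toc = 0.079
    return CatchmentSpec(
        nodes=(
            NodeSpec("WWTP", NodeKind.WWTP, flow=1.0),
            NodeSpec(
                "CHANNEL",
                NodeKind.CHANNEL,
                upstream=("WWTP",),
                toc_fraction=toc,
            ),
        ),
        compounds=(
            CompoundTruth(
                name="tracer",
                influent_ng_L=influent_ng_L,
                removal_percent=removal_percent,
                kd_L_kg=kd_L_kg,
            ),
        ),
        noise_sigma=noise_sigma,
        lod_ng_L=lod_ng_L,
        lod_ng_kg=lod_ng_kg,
        reference_toc=toc,
        seed=seed,
    )
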