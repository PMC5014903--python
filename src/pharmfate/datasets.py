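"""Bundled survey dataset: a six-pharmaceutical source/sink survey of a
southern-Swedish wetland catchment (seven sampling points SP1-SP7 along a
river -> WWTP -> channel -> lake path, plus a landfill leachate source).

The fixtures cover every pipeline stage: the compound registry with
physicochemical properties, the 2011 regional consumption statistics in
defined daily doses, the literature ecotoxicity endpoints, the lake and
leachate concentrations, and a noise-free reference catchment whose truth
parameters are set to the surveyed removal efficiencies and distribution
coefficients so that a full pipeline run echoes the survey's summary tables.

Channel water concentrations are NOT field values: they are back-computed
from the reported sediment concentrations and distribution coefficients
(e.g. 8000 ng/kg / 9.4 L/kg = 851 ng/L) and are labelled as reconstructed
wherever they appear.
"""

from __future__ import annotations

from pathlib import Path

from .quantities import Qualifier, Quantity, Unit
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
from .simulate import CatchmentSpec, CompoundTruth, NodeKind, NodeSpec

#: default configuration bridges between region statistics and plants;
#: explicit config values, not survey observations
REGION = "Skåne"
YEAR = 2011
REGION_POPULATION = 1_250_000
WASTEWATER_L_PER_CAPITA_DAY = 200.0
PLANT_POPULATION = {"SP2": 12_000, "SP5": 55_000}


def compound_registry() -> dict[str, Compound]:
    """The six study compounds with molecular weight (g/mol), acidity
    constant, water solubility (mg/L), log P, excretion-fraction interval
    and charge class at pH 7."""
    compounds = [
        Compound("atenolol", 266.3, 13300.0, 0.16, pka=9.6,
                 f_excreted_unchanged=(0.50, 0.90),
                 charge_class=ChargeClass.BASIC),
        Compound("bendroflumethiazide", 421.4, 108.0, 1.89, pka=8.5,
                 f_excreted_unchanged=(0.30, 0.30),
                 charge_class=ChargeClass.ACIDIC),
        Compound("carbamazepine", 236.3, 17.7, 2.45, pka=None,
                 f_excreted_unchanged=(0.02, 0.28),
                 charge_class=ChargeClass.NEUTRAL),
        Compound("diclofenac", 296.1, 2.37, 4.51, pka=4.15,
                 f_excreted_unchanged=(0.01, 0.15),
                 charge_class=ChargeClass.ACIDIC),
        # the literature disagrees sharply on furosemide excretion ("minute
        # amounts" vs 90 % unchanged); the interval records the conflict
        Compound("furosemide", 330.7, 73.1, 2.03, pka=4.25,
                 f_excreted_unchanged=(0.05, 0.90),
                 charge_class=ChargeClass.ACIDIC),
        Compound("oxazepam", 286.7, 179.0, 2.24, pka=None,
                 f_excreted_unchanged=(1.0, 1.0),
                 charge_class=ChargeClass.NEUTRAL),
    ]
    return {c.name: c for c in compounds}


def consumption_records() -> list[ConsumptionRecord]:
    """2011 regional consumption in DDD counts and DDD sizes (mg)."""
    rows = [
        ("atenolol", 6_003_685, 75.0),
        ("bendroflumethiazide", 10_858_173, 2.5),
        ("carbamazepine", 720_960, 1000.0),
        ("diclofenac", 8_967_462, 100.0),
        ("furosemide", 17_994_005, 40.0),
        ("oxazepam", 1_730_691, 50.0),
    ]
    return [
        ConsumptionRecord(name, n, mg, region=REGION, year=YEAR,
                          population=REGION_POPULATION)
        for name, n, mg in rows
    ]


def sampling_sites() -> list[SamplingSite]:
    return [
        SamplingSite("SP1", SiteKind.RIVER,
                     "Helge Å at Brunkelstorp, upstream reference"),
        SamplingSite("SP2", SiteKind.WWTP, "Osby WWTP (12,000 persons)"),
        SamplingSite("SP3", SiteKind.LAKE, "Lake Osbysjön"),
        SamplingSite("SP4", SiteKind.LANDFILL,
                     "Härlöv landfill leachate"),
        SamplingSite("SP5", SiteKind.WWTP,
                     "Kristianstad WWTP (150,000 p.e.)"),
        SamplingSite("SP6", SiteKind.CHANNEL,
                     "1500 m discharge channel"),
        SamplingSite("SP7", SiteKind.LAKE, "Lake Hammarsjön"),
    ]


def tox_endpoints() -> list[ToxEndpoint]:
    """Most sensitive chronic endpoints found in the ecotoxicological
    literature for five of the six compounds; none are usable for
    bendroflumethiazide."""
    return [
        ToxEndpoint("atenolol", "Pimephales promelas",
                    "21-day adult reproduction (condition index)",
                    EndpointType.NOEC, Quantity(1.0, Unit.MG_PER_L),
                    source="Winter et al. 2008"),
        ToxEndpoint("carbamazepine", "Ceriodaphnia dubia",
                    "7-day reproduction", EndpointType.NOEC,
                    Quantity(25_000.0, Unit.NG_PER_L),
                    source="Ferrari et al. 2003"),
        ToxEndpoint("diclofenac", "Danio rerio", "72-h embryo test",
                    EndpointType.NOEC, Quantity(1.5, Unit.MG_PER_L),
                    source="van den Brandhof & Montforts 2010"),
        ToxEndpoint("furosemide", "Ceriodaphnia dubia", "population growth",
                    EndpointType.NOEC, Quantity(156.0, Unit.UG_PER_L),
                    source="Isidori et al. 2006"),
        ToxEndpoint("oxazepam", "Oryzias latipes", "larval behaviour",
                    EndpointType.LOEC, Quantity(10.0, Unit.UG_PER_L),
                    source="Chiffre et al. 2016"),
    ]


#: surveyed surface-water concentrations in Lake Hammarsjön (SP7), ng/L
LAKE_MEC_NG_L = {
    "atenolol": 331.0,
    "bendroflumethiazide": 0.7,
    "carbamazepine": 161.0,
    "diclofenac": 119.0,
    "furosemide": 100.0,
    "oxazepam": 115.0,
}

#: landfill leachate concentrations (SP4), ng/L
LEACHATE_NG_L = {
    "carbamazepine": 54.0,
    "diclofenac": 192.0,
    "furosemide": 46.0,
    "oxazepam": 15.0,
}

#: surveyed channel sediment lower bounds (SP6), ng/kg dry weight
CHANNEL_SEDIMENT_NG_KG = {
    "atenolol": 8000.0,
    "carbamazepine": 55_000.0,
    "diclofenac": 11_000.0,
    "furosemide": 350_000.0,
    "oxazepam": 100_000.0,
}

#: surveyed distribution coefficients at the channel, L/kg
CHANNEL_KD_L_KG = {
    "atenolol": 9.4,
    "carbamazepine": 125.0,
    "diclofenac": 62.0,
    "furosemide": 2517.0,
    "oxazepam": 402.0,
}

CHANNEL_TOC = 0.079
LAKE_TOC = 0.0043


def lake_measurements() -> list[Measurement]:
    """Surface-water measurements at Lake Hammarsjön (SP7)."""
    return [
        Measurement("SP7", name, Matrix.SURFACE_WATER,
                    Quantity(value, Unit.NG_PER_L))
        for name, value in sorted(LAKE_MEC_NG_L.items())
    ]


def leachate_measurements() -> list[Measurement]:
    out = [
        Measurement("SP4", name, Matrix.LEACHATE,
                    Quantity(value, Unit.NG_PER_L))
        for name, value in sorted(LEACHATE_NG_L.items())
    ]
    for absent in ("atenolol", "bendroflumethiazide"):
        out.append(
            Measurement("SP4", absent, Matrix.LEACHATE,
                        Quantity(None, Unit.NG_PER_L, Qualifier.NOT_DETECTED))
        )
    return out


def channel_measurements(censored_sediment: bool = True) -> list[Measurement]:
    """Channel (SP6) sediment and water pairs.

    Sediment values are the surveyed lower bounds (">" qualifier when
    ``censored_sediment``).  The water concentrations are RECONSTRUCTED from
    sediment / K_d so the surveyed coefficients emerge from the pair; they
    are not field observations."""
    out = []
    for name in sorted(CHANNEL_SEDIMENT_NG_KG):
        sed = CHANNEL_SEDIMENT_NG_KG[name]
        qualifier = Qualifier.GREATER_THAN if censored_sediment else Qualifier.EXACT
        out.append(
            Measurement("SP6", name, Matrix.SEDIMENT,
                        Quantity(sed, Unit.NG_PER_KG, qualifier),
                        toc_fraction=CHANNEL_TOC)
        )
        water = sed / CHANNEL_KD_L_KG[name]
        out.append(
            Measurement("SP6", name, Matrix.SURFACE_WATER,
                        Quantity(water, Unit.NG_PER_L))
        )
    out.append(
        Measurement("SP6", "bendroflumethiazide", Matrix.SEDIMENT,
                    Quantity(None, Unit.NG_PER_KG, Qualifier.NOT_DETECTED),
                    toc_fraction=CHANNEL_TOC)
    )
    return out


def study_measurements() -> list[Measurement]:
    """All bundled field-style measurements (lake, leachate, channel)."""
    return lake_measurements() + leachate_measurements() + channel_measurements()


def fixture_measurements() -> list[Measurement]:
    """Complete measurement set exercising every pipeline stage: the
    field-style lake/leachate/channel records plus the WWTP influent and
    effluent pairs of the noise-free reference catchment (the surveyed
    treatment concentrations exist only as figures, so the pairs here are
    synthetic values whose removal ratios equal the surveyed table)."""
    from .simulate import simulate

    wwtp = [
        m
        for m in simulate(reference_catchment()).measurements
        if m.matrix in (Matrix.INFLUENT, Matrix.EFFLUENT)
    ]
    return study_measurements() + wwtp


def reference_catchment() -> CatchmentSpec:
    """Noise-free catchment whose truth parameters reproduce the surveyed
    removal table and distribution coefficients when the pipeline runs on
    its output.

    Influent levels are set inside the concentration ranges the survey
    reports in prose; relative flows are invented scenario parameters (the
    survey gives none) and are labelled as such in the emitted truth file.
    LOD is zero so complete removal appears as an exact 100 % rather than a
    censored bound.
    """
    grab = SampleType.GRAB.value
    day = SampleType.COMPOSITE_24H.value
    compounds = (
        CompoundTruth(
            "atenolol",
            influent_ng_L={"SP2": 1000.0, "SP5": 5800.0},
            removal_percent={"SP2": 89.0, "SP5": {grab: 73.0, day: 100.0}},
            kd_L_kg=9.4,
        ),
        CompoundTruth(
            "bendroflumethiazide",
            influent_ng_L={"SP2": 10.0, "SP5": 12.0},
            removal_percent={"SP2": 100.0, "SP5": {grab: 89.0, day: 67.0}},
            kd_L_kg=0.0,
        ),
        CompoundTruth(
            "carbamazepine",
            influent_ng_L={"SP2": 510.0, "SP5": 1500.0},
            removal_percent={"SP2": 84.0, "SP5": {grab: 97.0, day: 48.0}},
            kd_L_kg=125.0,
            leachate_ng_L=54.0,
        ),
        CompoundTruth(
            "diclofenac",
            influent_ng_L={"SP2": 700.0, "SP5": 700.0},
            removal_percent={"SP2": 81.0, "SP5": {grab: 38.0, day: 12.0}},
            kd_L_kg=62.0,
            leachate_ng_L=192.0,
        ),
        CompoundTruth(
            "furosemide",
            influent_ng_L={"SP2": 300.0, "SP5": 410.0},
            removal_percent={"SP2": -34.0, "SP5": {grab: 44.0, day: -7.0}},
            kd_L_kg=2517.0,
            leachate_ng_L=46.0,
        ),
        CompoundTruth(
            "oxazepam",
            influent_ng_L={"SP2": 400.0, "SP5": 600.0},
            removal_percent={"SP2": 76.0, "SP5": {grab: 89.0, day: 34.0}},
            kd_L_kg=402.0,
            leachate_ng_L=15.0,
        ),
    )
    nodes = (
        NodeSpec("SP1", NodeKind.RIVER_SOURCE, flow=10.0,
                 description="upstream river reference"),
        NodeSpec("SP2", NodeKind.WWTP, flow=0.2,
                 description="small WWTP (12,000 persons)"),
        NodeSpec("SP3", NodeKind.LAKE, upstream=("SP1", "SP2"),
                 description="receiving lake, strong dilution"),
        NodeSpec("SP4", NodeKind.LANDFILL, flow=0.05,
                 description="landfill leachate"),
        NodeSpec("SP5", NodeKind.WWTP, flow=1.0,
                 sample_types=(SampleType.GRAB, SampleType.COMPOSITE_24H),
                 description="large WWTP (150,000 p.e.)"),
        NodeSpec("SP6", NodeKind.CHANNEL, upstream=("SP5",),
                 toc_fraction=CHANNEL_TOC,
                 description="slow discharge channel, organic-rich sediment"),
        NodeSpec("SP7", NodeKind.LAKE, upstream=("SP6",),
                 dilution_factor=2.5, toc_fraction=LAKE_TOC,
                 description="receiving lake, organic-poor sediment"),
    )
    return CatchmentSpec(
        nodes=nodes,
        compounds=compounds,
        noise_sigma=0.0,
        lod_ng_L=0.0,
        lod_ng_kg=0.0,
        reference_toc=CHANNEL_TOC,
        seed=0,
    )


def write_fixture_csvs(outdir: str | Path) -> list[Path]:
    """Write the full fixture family (compounds, sites, consumption,
    endpoints, measurements) as CSVs plus the reference-catchment dataset."""
    from .io import (
        write_compounds,
        write_consumption,
        write_endpoints,
        write_measurements,
        write_sites,
    )
    from .simulate import simulate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(fn, data, name):
        path = outdir / name
        fn(data, path)
        written.append(path)

    _w(write_compounds, list(compound_registry().values()), "compounds.csv")
    _w(write_sites, sampling_sites(), "sites.csv")
    _w(write_consumption, consumption_records(), "consumption.csv")
    _w(write_endpoints, tox_endpoints(), "endpoints.csv")
    _w(write_measurements, fixture_measurements(), "measurements.csv")
    sim_dir = outdir / "reference_catchment"
    simulate(reference_catchment()).to_dir(sim_dir)
    written += sorted(sim_dir.iterdir())
    return written
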