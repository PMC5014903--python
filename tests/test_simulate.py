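"""Catchment simulator: propagation physics, determinism, recovery."""

import numpy as np
import pytest

from pharmfate.datasets import reference_catchment
from pharmfate.quantities import Qualifier
from pharmfate.records import Matrix, SampleType
from pharmfate.simulate import (
    CatchmentSpec,
    CatchmentSpecError,
    CompoundTruth,
    NodeKind,
    NodeSpec,
    recover,
    simple_catchment,
    simulate,
    spec_from_yaml,
    steady_state,
)


def _by_key(dataset):
    return {
        (m.site, m.compound, m.matrix, m.sample_type): m.quantity
        for m in dataset.measurements
    }


def _two_source_junction(dilution=1.0):
    return CatchmentSpec(
        nodes=(
            NodeSpec("A", NodeKind.RIVER_SOURCE, flow=3.0, source_ng_L=100.0),
            NodeSpec("B", NodeKind.RIVER_SOURCE, flow=1.0, source_ng_L=500.0),
            NodeSpec("J", NodeKind.LAKE, upstream=("A", "B"),
                     dilution_factor=dilution),
        ),
        compounds=(CompoundTruth("x"),),
        noise_sigma=0.0,
        lod_ng_L=0.0,
        lod_ng_kg=0.0,
        seed=1,
    )


class TestPropagation:
    def test_effluent_is_influent_times_removal(self):
        spec = simple_catchment(removal_percent=70.0, influent_ng_L=1000.0,
                                noise_sigma=0.0)
        q = _by_key(simulate(spec))
        assert q[("WWTP", "tracer", Matrix.EFFLUENT, SampleType.GRAB)].value == 300.0

    def test_sediment_is_kd_times_water_at_reference_toc(self):
        spec = simple_catchment(removal_percent=80.0, kd_L_kg=100.0,
                                influent_ng_L=1000.0, noise_sigma=0.0)
        q = _by_key(simulate(spec))
        water = q[("CHANNEL", "tracer", Matrix.SURFACE_WATER, SampleType.GRAB)]
        sed = q[("CHANNEL", "tracer", Matrix.SEDIMENT, SampleType.GRAB)]
        assert water.value == 200.0
        assert sed.value == 20_000.0

    def test_junction_mass_balance(self):
        spec = _two_source_junction()
        conc = steady_state(spec)
        # sum(Q_i C_i) = Q_out C_out exactly at sigma = 0
        assert 3.0 * 100.0 + 1.0 * 500.0 == pytest.approx(
            4.0 * conc["J"]["x"]
        )
        assert conc["J"]["x"] == pytest.approx(200.0)

    def test_dilution_factor_conserves_contaminant_mass(self):
        conc = steady_state(_two_source_junction(dilution=2.0))
        # outflow 4 * 2 = 8, concentration halved: mass unchanged
        assert 8.0 * conc["J"]["x"] == pytest.approx(800.0)

    def test_monotone_dilution_along_sourceless_path(self):
        spec = reference_catchment()
        conc = steady_state(spec)
        # WWTP effluent -> channel -> lake: no new sources downstream
        for compound in conc["SP6"]:
            assert conc["SP6"][compound] <= conc["SP5"][compound] + 1e-12
            assert conc["SP7"][compound] <= conc["SP6"][compound] + 1e-12

    def test_forward_reference_rejected(self):
        with pytest.raises(CatchmentSpecError):
            CatchmentSpec(
                nodes=(
                    NodeSpec("A", NodeKind.LAKE, upstream=("B",)),
                    NodeSpec("B", NodeKind.RIVER_SOURCE),
                ),
                compounds=(CompoundTruth("x"),),
            )

    def test_duplicate_node_id_rejected(self):
        with pytest.raises(CatchmentSpecError):
            CatchmentSpec(
                nodes=(
                    NodeSpec("A", NodeKind.RIVER_SOURCE),
                    NodeSpec("A", NodeKind.RIVER_SOURCE),
                ),
                compounds=(CompoundTruth("x"),),
            )


class TestDeterminismAndCensoring:
    def test_same_seed_identical_files(self, tmp_path):
        spec = simple_catchment(noise_sigma=0.1, seed=7)
        simulate(spec).to_dir(tmp_path / "a")
        simulate(spec).to_dir(tmp_path / "b")
        for name in ("sites.csv", "measurements.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        spec = simple_catchment(noise_sigma=0.1)
        a = simulate(spec, seed=1)
        b = simulate(spec, seed=2)
        values_a = [m.quantity.value for m in a.measurements]
        values_b = [m.quantity.value for m in b.measurements]
        assert values_a != values_b

    def test_values_below_lod_censored_at_lod(self):
        spec = simple_catchment(removal_percent=99.99, influent_ng_L=100.0,
                                noise_sigma=0.0, lod_ng_L=5.0)
        q = _by_key(simulate(spec))
        effluent = q[("WWTP", "tracer", Matrix.EFFLUENT, SampleType.GRAB)]
        assert effluent.qualifier is Qualifier.LESS_THAN
        assert effluent.value == 5.0

    def test_lod_above_truth_censors_every_estimate(self):
        spec = simple_catchment(removal_percent=50.0, influent_ng_L=10.0,
                                kd_L_kg=1.0, noise_sigma=0.0,
                                lod_ng_L=1e6, lod_ng_kg=1e9)
        rec = recover(simulate(spec))
        assert rec.removal and rec.kd
        for r in list(rec.removal) + list(rec.kd):
            assert r.estimate is None
            assert r.flags  # censored / indeterminate, never silently numeric

    def test_yaml_round_trip(self, tmp_path):
        spec = simple_catchment(noise_sigma=0.05, seed=3)
        out = tmp_path / "sim"
        simulate(spec).to_dir(out)
        import json

        truth = json.loads((out / "truth.json").read_text())
        yaml_path = tmp_path / "spec.yaml"
        import yaml as _yaml

        yaml_path.write_text(_yaml.safe_dump(truth["spec"]))
        reloaded = spec_from_yaml(yaml_path)
        assert reloaded.noise_sigma == spec.noise_sigma
        assert [n.id for n in reloaded.nodes] == [n.id for n in spec.nodes]
        a = simulate(spec).measurements_frame()
        b = simulate(reloaded).measurements_frame()
        assert a.equals(b)


class TestRecovery:
    def test_zero_noise_recovers_truth_exactly(self):
        rec = recover(simulate(simple_catchment(noise_sigma=0.0)))
        for r in rec.removal:
            assert r.error == pytest.approx(0.0, abs=1e-9)
        for r in rec.kd:
            assert r.error == pytest.approx(0.0, abs=1e-9)

    def test_bias_shrinks_with_noise(self):
        """Median recovery error decreases towards zero as sigma -> 0."""
        medians = {}
        for sigma in (0.1, 0.01, 0.0):
            errors = []
            for seed in range(60):
                rec = recover(
                    simulate(simple_catchment(noise_sigma=sigma, seed=seed))
                )
                errors.extend(abs(r.error) for r in rec.removal)
            medians[sigma] = float(np.median(errors))
        assert medians[0.0] == pytest.approx(0.0, abs=1e-9)
        assert medians[0.01] < medians[0.1]
        assert medians[0.01] < 1.0

    def test_reference_catchment_echoes_survey_tables(self):
        """The noise-free reference scenario reproduces the surveyed removal
        matrix and distribution coefficients through the estimators."""
        rec = recover(simulate(reference_catchment()))
        removal = {
            (r.plant, r.compound, r.sample_type): r.estimate
            for r in rec.removal
        }
        assert removal[("SP2", "atenolol", SampleType.GRAB)] == pytest.approx(89.0)
        assert removal[("SP5", "furosemide", SampleType.GRAB)] == pytest.approx(44.0)
        assert removal[("SP2", "furosemide", SampleType.GRAB)] == pytest.approx(-34.0)
        assert removal[
            ("SP5", "atenolol", SampleType.COMPOSITE_24H)
        ] == pytest.approx(100.0)
        kd_channel = {
            r.compound: r.estimate for r in rec.kd if r.site == "SP6"
        }
        assert kd_channel["atenolol"] == pytest.approx(9.4)
        assert kd_channel["carbamazepine"] == pytest.approx(125.0)
        assert kd_channel["furosemide"] == pytest.approx(2517.0)
        assert kd_channel["oxazepam"] == pytest.approx(402.0)
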