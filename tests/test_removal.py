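"""Influent/effluent removal efficiency and the removal table."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmfate.quantities import Qualifier, Quantity, Unit
from pharmfate.records import Matrix, Measurement, SampleType
from pharmfate.removal import (
    AmbiguousPairError,
    InfluentEffluentPair,
    RemovalFlag,
    UndefinedRemovalError,
    pairs_from_measurements,
    removal_efficiency,
    removal_table,
)


def _pair(c_in, c_out, q_in=Qualifier.EXACT, q_out=Qualifier.EXACT,
          sample_type=SampleType.GRAB):
    return InfluentEffluentPair(
        plant="P",
        compound="x",
        influent=Quantity(c_in, Unit.NG_PER_L, q_in),
        effluent=Quantity(c_out, Unit.NG_PER_L, q_out),
        sample_type=sample_type,
    )


class TestRemovalEfficiency:
    def test_complete_removal(self):
        res = removal_efficiency(_pair(100.0, 0.0))
        assert res.efficiency_percent == 100.0
        assert res.qualifier is Qualifier.EXACT

    def test_negative_removal_preserved_and_flagged(self):
        res = removal_efficiency(_pair(400.0, 500.0))
        assert res.efficiency_percent == -25.0
        assert RemovalFlag.NEGATIVE_REMOVAL in res.flags
        assert res.table_value == "-25"

    def test_censored_effluent_gives_lower_bound(self):
        res = removal_efficiency(_pair(1000.0, 50.0, q_out=Qualifier.LESS_THAN))
        assert res.efficiency_percent == 95.0
        assert res.qualifier is Qualifier.AT_LEAST
        assert RemovalFlag.CENSORED in res.flags
        assert res.table_value == "≥95"

    def test_censored_influent_gives_upper_bound(self):
        res = removal_efficiency(_pair(100.0, 10.0, q_in=Qualifier.LESS_THAN))
        assert res.qualifier is Qualifier.AT_MOST

    def test_both_censored_same_direction_is_indeterminate(self):
        res = removal_efficiency(
            _pair(100.0, 10.0, q_in=Qualifier.LESS_THAN,
                  q_out=Qualifier.LESS_THAN)
        )
        assert res.qualifier is Qualifier.INDETERMINATE
        assert RemovalFlag.INDETERMINATE in res.flags

    def test_nondetect_influent_is_undefined(self):
        with pytest.raises(UndefinedRemovalError):
            removal_efficiency(
                _pair(5.0, 1.0, q_in=Qualifier.NOT_DETECTED)
            )

    def test_zero_influent_is_undefined(self):
        with pytest.raises(UndefinedRemovalError):
            removal_efficiency(_pair(0.0, 0.0))

    def test_bounded_above_by_100_for_exact_inputs(self):
        res = removal_efficiency(_pair(123.4, 0.0))
        assert res.efficiency_percent <= 100.0

    def test_identity_gives_zero(self):
        assert removal_efficiency(_pair(77.0, 77.0)).efficiency_percent == 0.0

    @settings(derandomize=True, max_examples=300)
    @given(
        c_in=st.floats(min_value=1.0, max_value=1e6),
        c_out=st.floats(min_value=0.0, max_value=1e6),
        k=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, c_in, c_out, k):
        base = removal_efficiency(_pair(c_in, c_out)).efficiency_percent
        scaled = removal_efficiency(_pair(k * c_in, k * c_out)).efficiency_percent
        assert scaled == pytest.approx(base, abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(
        c_in=st.floats(min_value=10.0, max_value=1e5),
        c_out=st.floats(min_value=0.0, max_value=1e5),
        bump=st.floats(min_value=0.1, max_value=1e4),
    )
    def test_strictly_decreasing_in_effluent(self, c_in, c_out, bump):
        low = removal_efficiency(_pair(c_in, c_out + bump)).efficiency_percent
        high = removal_efficiency(_pair(c_in, c_out)).efficiency_percent
        assert low < high


def _measurement(site, compound, matrix, value, sample_type=SampleType.GRAB):
    return Measurement(
        site, compound, matrix, Quantity(value, Unit.NG_PER_L), sample_type
    )


class TestPairingAndTable:
    def test_pairs_matched_by_site_compound_sample_type(self):
        ms = [
            _measurement("P1", "a", Matrix.INFLUENT, 100.0),
            _measurement("P1", "a", Matrix.EFFLUENT, 40.0),
            _measurement("P1", "a", Matrix.INFLUENT, 90.0, SampleType.COMPOSITE_24H),
            _measurement("P1", "a", Matrix.EFFLUENT, 30.0, SampleType.COMPOSITE_24H),
            # unmatched influent is skipped, not an error
            _measurement("P2", "a", Matrix.INFLUENT, 50.0),
        ]
        pairs = pairs_from_measurements(ms)
        assert len(pairs) == 2
        assert {p.sample_type for p in pairs} == {
            SampleType.GRAB, SampleType.COMPOSITE_24H
        }

    def test_duplicate_matrix_in_cell_is_ambiguous(self):
        ms = [
            _measurement("P1", "a", Matrix.INFLUENT, 100.0),
            _measurement("P1", "a", Matrix.INFLUENT, 120.0),
        ]
        with pytest.raises(AmbiguousPairError):
            pairs_from_measurements(ms)

    def test_table_shape_and_na_cells(self):
        pairs = [
            _pair(100.0, 10.0),
        ]
        results = [removal_efficiency(p) for p in pairs]
        # second compound only measured at a second plant
        other = removal_efficiency(
            InfluentEffluentPair(
                "Q", "y",
                Quantity(100.0, Unit.NG_PER_L),
                Quantity(50.0, Unit.NG_PER_L),
            )
        )
        table = removal_table(results + [other])
        assert table.shape == (2, 2)
        assert table.loc["x", ("P", "grab")] == "90"
        assert table.loc["x", ("Q", "grab")] == "NA"
        assert table.loc["y", ("Q", "grab")] == "50"

    def test_duplicate_cell_in_table_is_ambiguous(self):
        res = removal_efficiency(_pair(100.0, 10.0))
        with pytest.raises(AmbiguousPairError):
            removal_table([res, res])

    def test_table_rounds_to_integer_percent_api_keeps_precision(self):
        res = removal_efficiency(_pair(300.0, 113.0))
        assert res.efficiency_percent == pytest.approx(62.3333333)
        assert res.table_value == "62"
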