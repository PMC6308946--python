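import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firegrade import (
    IndexEquations,
    PhenologyConfig,
    classify_grade,
    composite_and_grade,
    index_a,
    index_b,
    index_c,
    index_d,
    index_e1,
    index_e2,
)
from firegrade.errors import StateError, ValidationError


class TestLogisticIndices:
    @pytest.mark.parametrize(
        "t_max,expected", [(15.0, 10.0), (27.5, 19.08)]
    )
    def test_temperature_scores(self, t_max, expected):
        assert index_a(t_max) == pytest.approx(expected, abs=0.01)

    def test_temperature_saturates_low(self):
        assert index_a(-40.0) < 1e-3

    @pytest.mark.parametrize(
        "rh,expected", [(0.75, 0.92), (0.25, 19.08), (0.50, 10.0)]
    )
    def test_humidity_scores(self, rh, expected):
        assert index_b(rh) == pytest.approx(expected, abs=0.01)

    def test_humidity_rejects_percent_scale(self):
        with pytest.raises(ValidationError):
            index_b(75.0)

    @pytest.mark.parametrize(
        "wind,expected", [(0.1, 3.78), (9.4, 19.68)]
    )
    def test_wind_scores(self, wind, expected):
        assert index_d(wind) == pytest.approx(expected, abs=0.01)

    def test_wind_rejects_negative(self):
        with pytest.raises(ValidationError):
            index_d(-1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            index_a(float("nan"))

    @given(st.tuples(st.floats(-50, 60), st.floats(-50, 60)))
    @settings(max_examples=50, derandomize=True)
    def test_temperature_strictly_increasing(self, pair):
        lo, hi = sorted(pair)
        if hi - lo > 1e-7:  # resolvable in the exponent's float arithmetic
            assert index_a(lo) < index_a(hi)

    @given(st.tuples(st.floats(0, 1), st.floats(0, 1)))
    @settings(max_examples=50, derandomize=True)
    def test_humidity_strictly_decreasing(self, pair):
        lo, hi = sorted(pair)
        if hi - lo > 1e-9:  # resolvable in the exponent's float arithmetic
            assert index_b(lo) > index_b(hi)

    @given(st.floats(0, 60))
    @settings(max_examples=50, derandomize=True)
    def test_wind_bounded_in_0_40(self, w):
        assert 0.0 < index_d(w) < 40.0


class TestPrecipitationIndex:
    def test_light_rain_no_dry_spell(self):
        assert index_c(0.3, 0) == pytest.approx(9.08, abs=0.01)

    def test_long_dry_spell_caps_at_50(self):
        assert index_c(0.0, 9) == 50.0

    def test_heavy_rain_branch(self):
        assert index_c(12.0, 3) == 10.0

    def test_heavy_rain_at_zero_run_clamps_to_zero(self):
        assert index_c(12.0, 0) == 0.0

    @given(st.tuples(st.floats(0, 10), st.floats(0, 10)))
    @settings(max_examples=50, derandomize=True)
    def test_logistic_part_decreasing_in_rain(self, pair):
        lo, hi = sorted(pair)
        if hi - lo > 1e-7:
            assert index_c(lo, 0) > index_c(hi, 0)

    @given(st.floats(0, 200), st.integers(0, 30))
    @settings(max_examples=100, derandomize=True)
    def test_always_within_0_50(self, precip, run):
        assert 0.0 <= index_c(precip, run) <= 50.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            index_c(-1.0, 0)
        with pytest.raises(ValidationError):
            index_c(0.0, -1)


class TestSoilMoistureCorrection:
    @pytest.mark.parametrize(
        "vwc,expected", [(0.04, 0.0), (0.175, -10.0), (0.35, -20.0)]
    )
    def test_piecewise_values(self, vwc, expected):
        assert index_e2(vwc) == pytest.approx(expected, abs=1e-12)

    def test_continuity_at_breakpoints(self):
        eps = 1e-12
        assert abs(index_e2(0.05 - eps) - index_e2(0.05)) < 1e-9
        assert abs(index_e2(0.30 - eps) - index_e2(0.30)) < 1e-9

    @given(st.tuples(st.floats(0, 1), st.floats(0, 1)))
    @settings(max_examples=50, derandomize=True)
    def test_non_increasing(self, pair):
        lo, hi = sorted(pair)
        assert index_e2(lo) >= index_e2(hi)

    def test_rejects_percent_scale(self):
        with pytest.raises(ValidationError):
            index_e2(35.0)


class TestPhenology:
    def test_core_season(self):
        assert index_e1(dt.date(2017, 4, 10)) == 20.0

    def test_fire_season_outside_core(self):
        assert index_e1(dt.date(2017, 3, 5)) == 15.0
        assert index_e1(dt.date(2017, 10, 1)) == 15.0

    def test_off_season(self):
        assert index_e1(dt.date(2017, 7, 15)) == 0.0

    def test_iso_string_accepted(self):
        assert index_e1("2017-04-10") == 20.0

    def test_malformed_date_rejected(self):
        with pytest.raises(ValidationError):
            index_e1("not-a-date")

    def test_core_must_nest_in_fire_season(self):
        with pytest.raises(ValidationError):
            PhenologyConfig(
                fire_season_ranges=(((3, 1), (5, 31)),),
                core_season_ranges=(((6, 1), (6, 30)),),
            )


class TestGrades:
    @pytest.mark.parametrize(
        "total,grade",
        [(0, 1), (25, 1), (25.4, 1), (25.5, 2), (26, 2), (50, 2),
         (50.5, 3), (60, 3), (72, 3), (73, 4), (90, 4), (90.5, 5), (95, 5)],
    )
    def test_threshold_table(self, total, grade):
        assert classify_grade(total) == grade

    def test_composite_is_plain_sum(self):
        total, grade = composite_and_grade(10, 10, 10, 10, 15, -20)
        assert total == pytest.approx(35.0)
        assert grade == 2

    def test_all_zero_components_grade_one(self):
        assert composite_and_grade(0, 0, 0, 0, 0, 0) == (0.0, 1)

    @given(st.tuples(st.floats(-20, 150), st.floats(-20, 150)))
    @settings(max_examples=100, derandomize=True)
    def test_grade_non_decreasing(self, pair):
        lo, hi = sorted(pair)
        assert classify_grade(lo) <= classify_grade(hi)


class TestIndexEquations:
    def test_requires_run_counter(self):
        eqs = IndexEquations.published()
        with pytest.raises(StateError):
            eqs.assess("2017-04-01", 20, 0.3, 0.0, 5.0, 0.1,
                       dry_run=None, wet_run=None)

    def test_wet_counter_binding(self):
        dry_eqs = IndexEquations.published(c_run_counter="dry")
        wet_eqs = IndexEquations.published(c_run_counter="wet")
        a_dry = dry_eqs.assess("2017-04-01", 20, 0.3, 12.0, 5.0, 0.1,
                               dry_run=0, wet_run=3)
        a_wet = wet_eqs.assess("2017-04-01", 20, 0.3, 12.0, 5.0, 0.1,
                               dry_run=0, wet_run=3)
        assert a_dry.y_c == 0.0         # 5*(0-1) clamped
        assert a_wet.y_c == 10.0        # 5*(3-1)

    def test_total_is_component_sum(self):
        a = IndexEquations.published().assess(
            "2017-04-01", 27.5, 0.25, 0.0, 20.7, 0.04, dry_run=9, wet_run=0
        )
        assert a.total == pytest.approx(
            a.y_a + a.y_b + a.y_c + a.y_d + a.y_e1 + a.y_e2
        )
        assert a.grade == 5
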