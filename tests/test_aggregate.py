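import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firegrade import (
    AggregationConfig,
    DailySummary,
    IndexEquations,
    SensorRecord,
    assess_series,
    summarize_day,
    summarize_series,
    update_runs,
)
from firegrade.aggregate import (
    frame_to_summaries,
    read_sensor_csv,
    summaries_to_frame,
    write_sensor_csv,
)
from firegrade.errors import (
    EmptyDayError,
    LowCoverageError,
    SequenceError,
    ValidationError,
)
from conftest import make_day_frame


def _summary(date, precip_total, **kw):
    defaults = dict(t_max=15.0, rh_min=0.4, wind_max=3.0, humus_vwc=0.15,
                    soil40_vwc=0.15, n_records=144, gap_flag=False)
    defaults.update(kw)
    return DailySummary(date=date, precip_total=precip_total, **defaults)


class TestSummarizeDay:
    def test_constant_channels(self):
        s = summarize_day(make_day_frame(air_temp=10.0))
        assert s.t_max == 10.0
        assert s.rh_min == 0.5
        assert s.n_records == 144
        assert not s.gap_flag

    def test_precip_sums_over_intervals(self):
        precip = np.zeros(144)
        precip[40:45] = 0.2
        s = summarize_day(make_day_frame(precip=precip))
        assert s.precip_total == pytest.approx(1.0)

    def test_extremes_not_means(self):
        temps = np.full(144, 8.0)
        temps[80] = 21.5
        rh = np.full(144, 0.6)
        rh[30] = 0.22
        s = summarize_day(make_day_frame(air_temp=temps, rel_humidity=rh))
        assert s.t_max == 21.5
        assert s.rh_min == 0.22

    def test_short_gap_interpolated(self):
        # 20-min gap in a linear ramp: the bridged values are on the line,
        # so the daily maximum is unchanged from the complete series
        ramp = np.linspace(0.0, 14.3, 144)
        df = make_day_frame(air_temp=ramp, drop_slots=(100, 101))
        s = summarize_day(df)
        assert not s.gap_flag
        assert s.t_max == pytest.approx(14.3)
        assert s.n_records == 142

    def test_long_gap_sets_flag(self):
        df = make_day_frame(drop_slots=tuple(range(60, 65)))  # 50 min
        s = summarize_day(df)
        assert s.gap_flag

    def test_permutation_and_duplication_invariance(self):
        df = make_day_frame(air_temp=np.linspace(5, 15, 144))
        shuffled = pd.concat([df.iloc[::-1], df.iloc[:20]], ignore_index=True)
        assert summarize_day(shuffled) == summarize_day(df)

    def test_empty_day_rejected(self):
        with pytest.raises(EmptyDayError):
            summarize_day(make_day_frame().iloc[0:0])

    def test_low_coverage_carries_partial_summary(self):
        df = make_day_frame(air_temp=12.0).iloc[:100]  # 100/144 < 0.8
        with pytest.raises(LowCoverageError) as exc:
            summarize_day(df)
        assert exc.value.partial.t_max == 12.0

    def test_multiple_stations_rejected(self):
        df = pd.concat(
            [make_day_frame(station_id="S1"), make_day_frame(station_id="S2")],
            ignore_index=True,
        )
        with pytest.raises(ValidationError):
            summarize_day(df)

    def test_humus_statistic_configurable(self):
        vwc = np.linspace(0.1, 0.3, 144)
        df = make_day_frame(soil_vwc_10cm=vwc)
        mean_s = summarize_day(df, AggregationConfig(humus_statistic="mean"))
        min_s = summarize_day(df, AggregationConfig(humus_statistic="min"))
        assert mean_s.humus_vwc == pytest.approx(0.2)
        assert min_s.humus_vwc == pytest.approx(0.1)


class TestRunCounters:
    def test_documented_sequences(self):
        dates = [dt.date(2017, 3, 1) + dt.timedelta(days=i) for i in range(4)]
        precs = [0.0, 0.0, 5.0, 0.0]
        prev = None
        dry, wet = [], []
        for d, p in zip(dates, precs):
            prev = update_runs(prev, _summary(d, p))
            dry.append(prev.dry_run)
            wet.append(prev.wet_run)
        assert dry == [1, 2, 0, 1]
        assert wet == [0, 0, 1, 0]

    def test_first_day_dry(self):
        s = update_runs(None, _summary(dt.date(2017, 3, 1), 0.0))
        assert (s.dry_run, s.wet_run) == (1, 0)

    def test_non_consecutive_rejected(self):
        prev = update_runs(None, _summary(dt.date(2017, 3, 1), 0.0))
        with pytest.raises(SequenceError):
            update_runs(prev, _summary(dt.date(2017, 3, 3), 0.0))

    @given(st.lists(st.floats(0, 20), min_size=1, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_exactly_one_counter_positive(self, precips):
        prev = None
        date = dt.date(2017, 3, 1)
        threshold = AggregationConfig().rain_day_threshold
        for i, p in enumerate(precips):
            prev = update_runs(prev, _summary(date + dt.timedelta(days=i), p))
            assert (prev.dry_run > 0) != (prev.wet_run > 0)
            expected_wet = p >= threshold
            assert (prev.wet_run > 0) == expected_wet


class TestAssessSeries:
    def test_rain_day_with_wet_soil_scores_lower(self):
        d1 = _summary(dt.date(2017, 4, 1), 0.0, humus_vwc=0.10)
        d2 = _summary(dt.date(2017, 4, 2), 15.0, humus_vwc=0.35)
        d1 = update_runs(None, d1)
        d2 = update_runs(d1, d2)
        a1, a2 = assess_series([d1, d2])
        assert a2.y_e2 == -20.0
        assert a2.total < a1.total

    def test_benign_weather_grade_one(self):
        s = update_runs(None, _summary(
            dt.date(2017, 4, 1), 25.0, t_max=0.0, rh_min=1.0, wind_max=0.0,
            humus_vwc=0.40,
        ))
        (a,) = assess_series([s])
        assert a.grade == 1

    def test_hot_dry_windy_day_grade_five(self):
        prev = None
        date = dt.date(2017, 4, 1)
        for i in range(9):
            prev = update_runs(prev, _summary(date + dt.timedelta(days=i), 0.0))
        extreme = update_runs(prev, _summary(
            date + dt.timedelta(days=9), 0.0, t_max=27.5, rh_min=0.25,
            wind_max=20.7, humus_vwc=0.04,
        ))
        (a,) = assess_series([extreme])
        assert a.grade == 5
        assert a.total == pytest.approx(145.6, abs=0.5)

    def test_rain_block_totals_below_adjacent_dry_days(self):
        # same temperature and wind throughout; three-day rain block inside
        precs = [0, 0, 15, 15, 15, 0, 0]
        prev = None
        summaries = []
        for i, p in enumerate(precs):
            humus = 0.35 if p > 0 else 0.12
            prev = update_runs(prev, _summary(
                dt.date(2017, 4, 1) + dt.timedelta(days=i), p, humus_vwc=humus
            ))
            summaries.append(prev)
        totals = [a.total for a in assess_series(summaries)]
        block = totals[2:5]
        outside = totals[:2] + totals[5:]
        assert max(block) < min(outside)

    def test_gap_flag_propagates_but_day_still_scored(self):
        s = update_runs(None, _summary(dt.date(2017, 4, 1), 0.0, gap_flag=True))
        (a,) = assess_series([s])
        assert a.quality_flag
        assert a.grade in range(1, 6)


class TestSeriesAndCsv:
    def test_missing_day_restarts_counters(self):
        frames = [
            make_day_frame(dt.date(2017, 3, 1)),
            make_day_frame(dt.date(2017, 3, 2)),
            make_day_frame(dt.date(2017, 3, 4)),  # 3 March missing entirely
        ]
        summaries = summarize_series(pd.concat(frames, ignore_index=True))
        assert [s.dry_run for s in summaries] == [1, 2, 1]

    def test_row_reorder_and_duplication_idempotent(self):
        df = pd.concat(
            [make_day_frame(dt.date(2017, 3, 1)),
             make_day_frame(dt.date(2017, 3, 2))],
            ignore_index=True,
        )
        noisy = pd.concat([df.iloc[::-1], df.iloc[10:50]], ignore_index=True)
        assert summarize_series(noisy) == summarize_series(df)

    def test_sensor_csv_round_trip(self, tmp_path):
        df = make_day_frame(air_temp=np.linspace(5, 15, 144))
        path = tmp_path / "sensors.csv"
        write_sensor_csv(df, path)
        back = read_sensor_csv(path)
        assert list(back.columns) == list(df.columns)
        assert np.allclose(back["air_temp"], df["air_temp"], atol=1e-4)
        assert np.allclose(back["rel_humidity"], df["rel_humidity"], atol=1e-6)
        assert summarize_day(back) == summarize_day(df)

    def test_summary_frame_round_trip(self):
        s = update_runs(None, _summary(dt.date(2017, 3, 1), 0.0))
        assert frame_to_summaries(summaries_to_frame([s])) == [s]

    def test_record_validation(self):
        with pytest.raises(ValidationError):
            SensorRecord(dt.datetime(2017, 3, 1), "S1", 90.0, 0.5, 1, 0, 0.2, 0.2)
        with pytest.raises(ValidationError):
            SensorRecord(dt.datetime(2017, 3, 1), "S1", 10.0, 50.0, 1, 0, 0.2, 0.2)
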