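"""Series container, CSV dialect, protocol arithmetic, maximality checks."""

import numpy as np
import pytest

from cpetvt import (
    FormatError,
    GasExchangeSeries,
    MaximalityCriteria,
    ProtocolSpec,
    ValidationError,
    check_maximality,
    exclude_warmup,
    read_cpet_csv,
    work_rate_at_time,
    write_cpet_csv,
)
from conftest import make_series


class TestSeriesInvariants:
    def test_non_uniform_grid_names_first_offending_index(self):
        time = 10.0 * np.arange(1, 21)
        time[12] = time[11] + 5.0  # 5-s step entering sample 12
        with pytest.raises(ValidationError, match="index 12"):
            GasExchangeSeries(time=time, vo2=np.ones(20), vco2=np.ones(20), ve=np.ones(20))

    @pytest.mark.parametrize("channel,bad", [("vo2", 0.0), ("vo2", -1.0), ("ve", 0.0)])
    def test_positivity(self, channel, bad):
        kw = {"vo2": np.ones(5), "vco2": np.ones(5), "ve": np.ones(5)}
        kw[channel] = kw[channel].copy()
        kw[channel][3] = bad
        with pytest.raises(ValidationError, match=f"{channel}.*index 3"):
            make_series(**kw)

    def test_rer_must_match_ratio(self):
        with pytest.raises(ValidationError, match="rer"):
            make_series([2.0, 2.0], [2.0, 2.0], [50.0, 50.0], rer=np.array([1.0, 1.1]))

    def test_unequal_channel_lengths(self):
        with pytest.raises(ValidationError, match="length"):
            make_series([1.0, 1.0], [1.0, 1.0], [20.0, 20.0], hr=np.array([100.0]))


class TestCsvRoundTrip:
    def test_round_trip_is_bit_identical(self, ramp_series, tmp_path):
        path = tmp_path / "test.csv"
        write_cpet_csv(ramp_series, path)
        back = read_cpet_csv(path)
        assert len(back) == 60
        for ch in ("time", "vo2", "vco2", "ve"):
            assert np.array_equal(getattr(back, ch), getattr(ramp_series, ch))

    def test_missing_mandatory_column_is_reported(self, tmp_path):
        path = tmp_path / "broken.csv"
        path.write_text("time,vo2,vco2\n10,1.0,0.9\n20,1.1,1.0\n")
        with pytest.raises(FormatError, match="ve"):
            read_cpet_csv(path)

    def test_work_filled_from_protocol_and_rer_recomputed(self, ramp_series, tmp_path, nominal):
        path = tmp_path / "test.csv"
        write_cpet_csv(ramp_series, path)
        back = read_cpet_csv(path, protocol=nominal)
        assert back.work is not None
        assert back.work[0] == 50.0  # warm-up wattage at t = 10 s
        assert np.allclose(back.rer, back.vco2 / back.vo2)

    def test_column_mapping_for_vendor_exports(self, tmp_path):
        path = tmp_path / "vendor.csv"
        path.write_text("Time,VO2 (L/min),VCO2 (L/min),VE (L/min)\n10,1.0,0.9,25\n20,1.1,1.0,27\n")
        series = read_cpet_csv(
            path, column_map={"VO2 (L/min)": "vo2", "VCO2 (L/min)": "vco2", "VE (L/min)": "ve"}
        )
        assert series.vo2[1] == 1.1


class TestWarmupExclusion:
    def test_nominal_600s_leaves_42_samples(self, ramp_series, nominal):
        post = exclude_warmup(ramp_series, nominal)
        assert len(post) == 42
        assert post.time[0] == 190.0 and post.time[-1] == 600.0
        assert len(ramp_series) == 60  # original untouched

    def test_zero_warmup_is_identity(self, ramp_series):
        proto = ProtocolSpec(50.0, 0.0, 25.0, 60.0)
        post = exclude_warmup(ramp_series, proto)
        assert np.array_equal(post.time, ramp_series.time)

    def test_test_shorter_than_warmup_errors(self, nominal):
        short = make_series(np.ones(15), np.ones(15), 20 * np.ones(15))  # ends at 150 s
        with pytest.raises(ValidationError):
            exclude_warmup(short, nominal)

    def test_partition_bookkeeping(self, ramp_series, nominal):
        post = exclude_warmup(ramp_series, nominal)
        n_warm = int((ramp_series.time <= nominal.warmup_duration).sum())
        assert len(post) + n_warm == len(ramp_series)


class TestWorkRate:
    @pytest.mark.parametrize(
        "t,variant,expected",
        [
            (100.0, "nominal", 50.0),
            (200.0, "nominal", 75.0),
            (200.0, "light", 60.0),
            (180.0, "nominal", 50.0),  # warm-up boundary instant
        ],
    )
    def test_examples(self, t, variant, expected):
        proto = ProtocolSpec.nominal() if variant == "nominal" else ProtocolSpec.light()
        assert work_rate_at_time(t, proto) == expected

    def test_negative_time_errors(self, nominal):
        with pytest.raises(ValidationError):
            work_rate_at_time(-1.0, nominal)

    def test_nondecreasing_with_jumps_of_one_increment(self, nominal):
        t = np.arange(0.0, 1200.0, 10.0)
        w = work_rate_at_time(t, nominal)
        jumps = np.diff(w)
        assert np.all(jumps >= 0)
        assert set(np.unique(jumps)) <= {0.0, nominal.increment}


class TestMaximality:
    def test_predicted_hrmax(self):
        assert MaximalityCriteria().predicted_hrmax(40.0) == pytest.approx(180.2)

    def test_all_five_criteria(self):
        series = make_series(
            [2.0, 2.2], [2.4, 2.82], [60.0, 70.0],
            hr=np.array([170.0, 175.0]), rpe=np.array([np.nan, 19.0]), subject_age=40.0,
        )
        v = check_maximality(series, plateau=True, rpm_fall=True)
        assert v.maximal and v.n_met == 5
        assert v.predicted_hrmax == pytest.approx(180.2)

    def test_three_criteria_is_not_maximal(self):
        series = make_series([2.0, 2.2], [2.4, 2.82], [60.0, 70.0])  # RER peak 1.28 only
        v = check_maximality(series, plateau=True, rpm_fall=True)
        assert v.n_met == 3 and not v.maximal

    def test_missing_channels_degrade_gracefully(self):
        series = make_series([2.0], [1.8], [50.0])
        v = check_maximality(series)
        assert not v.maximal and v.predicted_hrmax is None
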