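import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import noisesleep as ns
from noisesleep.exposure import ExposureError


def oracle_lnight(lden, tt, ps=None):
    """Energy-balance oracle: explicit hourly schedule summation.

    Spread each period's events uniformly over its hours, sum penalized
    event energies into Lden, and read the night level off the same
    schedule. Independent of the closed-form conversion.
    """
    ps = ps or ns.PeriodScheme()
    hours = []  # (rate per hour, penalty, is_night)
    hours += [(tt.n_day / ps.day_hours, ps.day_penalty, False)] * int(round(ps.day_hours))
    hours += [(tt.n_evening / ps.evening_hours, ps.evening_penalty, False)] * int(round(ps.evening_hours))
    hours += [(tt.n_night / ps.night_hours, ps.night_penalty, True)] * int(round(ps.night_hours))
    rate = np.array([h[0] for h in hours])
    pen = np.array([h[1] for h in hours])
    night = np.array([h[2] for h in hours])
    lden_rel = 10 * np.log10(np.mean(rate * 10 ** (pen / 10)))
    lnight_rel = 10 * np.log10(np.mean(rate[night]))
    return lden - lden_rel + lnight_rel


class TestRoadOffset:
    def test_offset_arithmetic(self):
        assert ns.lnight_from_lden_road(60.0, 6.0) == pytest.approx(54.0)

    def test_zero_offset_is_identity(self):
        assert ns.lnight_from_lden_road(47.3, 0.0) == pytest.approx(47.3)

    def test_round_trip(self):
        lden = 63.7
        assert ns.lnight_from_lden_road(lden, 8.5) + 8.5 == pytest.approx(lden)


class TestTimetableConversion:
    def test_all_events_at_night_closed_form(self):
        # only the night term survives: lnight = lden - 10 + 10*log10(24/9)
        tt = ns.Timetable(0, 0, 120)
        expected_shift = -10 + 10 * np.log10(24 / 9)
        assert ns.lnight_from_timetable(50.0, tt) == pytest.approx(50.0 + expected_shift, abs=1e-9)

    def test_equal_hourly_rates(self):
        # rates equal in all periods: counts proportional to durations
        tt = ns.Timetable(120, 30, 90)
        expected = 60.0 - 10 * np.log10((120 + 30 * 10**0.5 + 90 * 10) / 24) + 10 * np.log10(90 / 9)
        assert ns.lnight_from_timetable(60.0, tt) == pytest.approx(expected, abs=1e-9)

    def test_no_night_traffic_is_an_error(self):
        with pytest.raises(ExposureError):
            ns.lnight_from_timetable(60.0, ns.Timetable(100, 10, 0))

    @pytest.mark.parametrize(
        "tt",
        [
            ns.Timetable(100, 20, 10),
            ns.Timetable(0, 0, 40),
            ns.Timetable(300, 0, 5),
            ns.Timetable(12, 3, 9),
        ],
    )
    def test_matches_energy_balance_oracle(self, tt):
        for lden in (40.0, 55.0, 70.0):
            assert ns.lnight_from_timetable(lden, tt) == pytest.approx(
                oracle_lnight(lden, tt), abs=1e-9
            )

    @given(
        nd=st.integers(0, 500),
        ne=st.integers(0, 100),
        nn=st.integers(1, 200),
        delta=st.floats(-20, 20),
    )
    def test_translation_equivariance(self, nd, ne, nn, delta):
        tt = ns.Timetable(nd, ne, nn)
        base = ns.lnight_from_timetable(55.0, tt)
        shifted = ns.lnight_from_timetable(55.0 + delta, tt)
        assert shifted == pytest.approx(base + delta, abs=1e-9)

    @given(nd=st.integers(0, 500), ne=st.integers(0, 100), nn=st.integers(1, 200))
    def test_doubling_counts_preserves_shift(self, nd, ne, nn):
        a = ns.lnight_from_timetable(55.0, ns.Timetable(nd, ne, nn))
        b = ns.lnight_from_timetable(55.0, ns.Timetable(2 * nd, 2 * ne, 2 * nn))
        assert a == pytest.approx(b, abs=1e-9)

    def test_period_scheme_must_partition_24h(self):
        with pytest.raises(ExposureError):
            ns.PeriodScheme(day_hours=12, evening_hours=3, night_hours=10)


class TestNlBinning:
    @pytest.mark.parametrize(
        "lnight, expected",
        [
            (51.0, 53),
            (55.0, 53),
            (53.0, 53),
            (55.5, 58),  # exact midpoint rounds to the upper class
            (50.5, 53),
            (30.0, 33),
            (80.4, 78),
        ],
    )
    def test_assignment(self, lnight, expected):
        assert ns.assign_nl_bin(lnight) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ExposureError):
            ns.assign_nl_bin(80.5)
        with pytest.raises(ExposureError):
            ns.assign_nl_bin(29.0)

    def test_partition_no_gaps_no_overlaps(self):
        grid = np.arange(30.5, 80.5, 0.001)
        centers = ns.assign_nl_bin(grid)
        # every level gets the nearest center; widths are 5 dB
        assert np.all(np.abs(grid - centers) <= 2.5 + 1e-9)
        edges = np.flatnonzero(np.diff(centers))
        assert len(edges) == len(ns.NL_CENTERS) - 1
        widths = np.diff(grid[edges])
        assert np.allclose(widths, 5.0, atol=0.01)

    def test_vectorized_matches_scalar_and_passes_nan(self):
        s = pd.Series([45.2, np.nan, 61.0])
        out = ns.nl_bins(s)
        assert out.tolist()[0] == ns.assign_nl_bin(45.2)
        assert np.isnan(out.iloc[1])


class TestResolveLnight:
    def _frame(self):
        return pd.DataFrame(
            {
                "dataset_id": ["d_road", "d_road", "d_rail", "d_direct"],
                "lnight_db": [np.nan, 44.0, np.nan, 50.0],
                "lden_db": [60.0, 60.0, 65.0, np.nan],
            }
        )

    def test_fills_only_missing_lnight(self):
        tt = ns.Timetable(100, 20, 10)
        cfgs = {
            "d_road": ns.ExposureConfig(mode="road_offset", day_night_diff=7.0),
            "d_rail": ns.ExposureConfig(mode="timetable", timetable=tt),
        }
        out = ns.resolve_lnight(self._frame(), cfgs)
        assert out["lnight_db"].iloc[0] == pytest.approx(53.0)
        assert out["lnight_db"].iloc[1] == 44.0  # supplied value untouched
        assert out["lnight_db"].iloc[2] == pytest.approx(
            ns.lnight_from_timetable(65.0, tt)
        )
        assert out["lnight_db"].iloc[3] == 50.0

    def test_config_validation(self):
        with pytest.raises(ExposureError):
            ns.ExposureConfig(mode="road_offset")
        with pytest.raises(ExposureError):
            ns.ExposureConfig(mode="timetable")
        with pytest.raises(ExposureError):
            ns.ExposureConfig(mode="nope")
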