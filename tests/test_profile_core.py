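"""CSV I/O, unit conversion and the complete-data-set rule."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melaphase.profile_core import (
    PGML_TO_PMOLL,
    PG_PER_ML,
    PMOL_PER_L,
    SampleSeries,
    check_completeness,
    convert_units,
    read_series,
    write_series,
)


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text)


class TestReadSeries:
    def test_basic_parse(self):
        out = read_series(_csv(
            "subject,day,time_h,concentration\nA,1,20.0,10\nA,1,20.5,20\nA,1,21.0,30\n"
        ), units=PMOL_PER_L)
        assert len(out) == 1
        s = out[0]
        assert s.subject_id == "A" and s.day_index == 1
        np.testing.assert_allclose(s.times, [20.0, 20.5, 21.0])
        np.testing.assert_allclose(s.concentrations, [10, 20, 30])

    def test_blank_concentration_is_a_gap_not_zero(self):
        out = read_series(_csv(
            "subject,day,time_h,concentration\nA,1,20.0,10\nA,1,20.5,\nA,1,21.0,30\n"
        ), units=PMOL_PER_L)
        s = out[0]
        assert len(s) == 2
        np.testing.assert_allclose(s.times, [20.0, 21.0])
        assert 0.0 not in s.concentrations

    def test_non_monotone_times_rejected_with_row(self):
        with pytest.raises(ValueError, match="row 3"):
            read_series(_csv(
                "subject,day,time_h,concentration\nA,1,21.0,10\nA,1,20.0,20\n"
            ), units=PMOL_PER_L)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_series(_csv(
                "subject,day,time_h,concentration\nA,1,20.0,-1\nA,1,21.0,5\n"
            ), units=PMOL_PER_L)

    def test_round_trip_bit_identical(self, tmp_path, noiseless_subject):
        days, _ = noiseless_subject
        path = tmp_path / "series.csv"
        write_series(days, path)
        back = read_series(path, units=PMOL_PER_L)
        assert len(back) == len(days)
        for a, b in zip(days, back):
            np.testing.assert_array_equal(a.times, b.times)
            np.testing.assert_array_equal(a.concentrations, b.concentrations)


class TestConvertUnits:
    def test_ten_pgml_is_exactly_43_08(self):
        s = SampleSeries("A", 1, np.array([20.0]), np.array([10.0]), PG_PER_ML)
        out = convert_units(s, PMOL_PER_L)
        assert out.concentrations[0] == pytest.approx(43.08, abs=1e-12)

    def test_zero_fixed_point(self):
        s = SampleSeries("A", 1, np.array([20.0]), np.array([0.0]), PG_PER_ML)
        assert convert_units(s, PMOL_PER_L).concentrations[0] == 0.0

    @given(st.lists(st.floats(0.0, 1e4), min_size=1, max_size=20))
    @settings(deadline=None)
    def test_round_trip_bijection(self, values):
        t = np.arange(len(values), dtype=float)
        s = SampleSeries("A", 1, t, np.array(values), PG_PER_ML)
        back = convert_units(convert_units(s, PMOL_PER_L), PG_PER_ML)
        np.testing.assert_allclose(back.concentrations, values, rtol=1e-12)

    def test_unknown_unit_tag(self):
        s = SampleSeries("A", 1, np.array([1.0]), np.array([1.0]), PMOL_PER_L)
        with pytest.raises(ValueError):
            convert_units(s, "nmol_per_L")


class TestCompleteness:
    @staticmethod
    def _hourly(missing=()):
        t = [h for h in range(25) if h not in missing]
        tt = np.array(t, dtype=float)
        return SampleSeries("A", 1, tt, np.ones_like(tt), PMOL_PER_L)

    def test_full_grid_complete(self):
        rep = check_completeness(self._hourly())
        assert rep.is_complete
        assert rep.max_consecutive_gap_h == 0.0
        assert rep.total_missing_h_per_24h == 0.0

    def test_single_hole_below_limit(self):
        # one missing hourly sample: 2-h interval = 1 h missing, still complete
        rep = check_completeness(self._hourly(missing={10}))
        assert rep.max_consecutive_gap_h == pytest.approx(1.0)
        assert rep.is_complete

    def test_long_hole_violates_consecutive_rule(self):
        # hours 10-12 missing: 4-h interval between 9 and 13 = 3 h missing
        rep = check_completeness(self._hourly(missing={10, 11, 12}))
        assert rep.max_consecutive_gap_h == pytest.approx(3.0)
        assert not rep.is_complete

    @pytest.mark.parametrize(
        "hole_starts, total, complete",
        [((4.0, 10.0, 16.0), 4.5, True), ((3.0, 8.0, 13.0, 18.0), 6.0, False)],
    )
    def test_total_missing_rule(self, hole_starts, total, complete):
        # 2.5-h sample-free intervals on a 30-min grid: each is 1.5 h missing
        # against the hourly schedule (under the 2-h consecutive limit), so
        # only their 24-h total decides completeness
        t = np.arange(0, 24.5, 0.5)
        keep = np.ones_like(t, dtype=bool)
        for start in hole_starts:
            keep &= ~((t > start) & (t < start + 2.5))
        tt = t[keep]
        s = SampleSeries("A", 1, tt, np.ones_like(tt), PMOL_PER_L)
        rep = check_completeness(s)
        assert rep.max_consecutive_gap_h == pytest.approx(1.5)
        assert rep.total_missing_h_per_24h == pytest.approx(total)
        assert rep.is_complete is complete

    def test_padding_with_full_hours_is_invariant(self):
        inner = self._hourly(missing={10, 11})
        rep1 = check_completeness(inner)
        t2 = np.concatenate([np.arange(-5.0, 0.0), inner.times,
                             np.arange(25.0, 30.0)])
        padded = SampleSeries("A", 1, t2, np.ones_like(t2), PMOL_PER_L)
        rep2 = check_completeness(padded)
        assert rep1.max_consecutive_gap_h == rep2.max_consecutive_gap_h
        assert rep1.total_missing_h_per_24h == rep2.total_missing_h_per_24h

    def test_single_sample_errors(self):
        s = SampleSeries("A", 1, np.array([1.0]), np.array([1.0]), PMOL_PER_L)
        with pytest.raises(ValueError):
            check_completeness(s)


class TestSampleSeries:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            SampleSeries("A", 1, np.array([1.0, 1.0]), np.array([1.0, 2.0]),
                         PMOL_PER_L)

    def test_negative_concentration_enforced(self):
        with pytest.raises(ValueError, match="negative"):
            SampleSeries("A", 1, np.array([1.0, 2.0]), np.array([1.0, -2.0]),
                         PMOL_PER_L)
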