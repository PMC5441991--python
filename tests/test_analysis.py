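"""Unwrapping, stitching, exclusion, inter-cochlear profiles and
across-sitting variability statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bccancel.analysis import (
    UnwrappedSeries,
    exclude_grade1,
    intercochlear_profile,
    paired_sd_test,
    records_to_frame,
    session_variability,
    stitch_sessions,
    unwrap_within_session,
)
from bccancel.psychophysics import TrialRecord


def _rec(session, freq, ear, grade, level=0.0, phase=0.0):
    return TrialRecord(session, freq, ear, level, phase, grade)


class TestExclusion:
    def test_all_good_grades_pass_through(self):
        df = records_to_frame(
            [_rec(0, 1000.0, "ipsi", 4), _rec(0, 1000.0, "contra", 4)]
        )
        out = exclude_grade1(df)
        assert len(out) == 2 and not out["excluded"].any()

    def test_grade1_drops_both_ears(self):
        df = records_to_frame(
            [
                _rec(0, 1000.0, "ipsi", 1),
                _rec(0, 1000.0, "contra", 4),
                _rec(0, 2000.0, "ipsi", 3),
                _rec(0, 2000.0, "contra", 3),
            ]
        )
        out = exclude_grade1(df)
        assert set(out["freq_hz"]) == {2000.0}

    def test_k_bad_trials_remove_2k_records(self):
        recs = []
        k = 0
        for s in range(3):
            for f in (1000.0, 2000.0, 3000.0):
                bad = (s + f / 1000) % 3 == 0
                g = 1 if bad else 4
                k += bad
                recs += [_rec(s, f, "ipsi", g), _rec(s, f, "contra", 4)]
        out = exclude_grade1(records_to_frame(recs))
        assert len(out) == len(recs) - 2 * k


class TestUnwrap:
    @pytest.mark.parametrize(
        "wrapped, expected",
        [
            ([350.0, 10.0], [350.0, 370.0]),
            ([10.0, 350.0], [10.0, -10.0]),
            ([0.0], [0.0]),
            ([90.0, 100.0, 110.0], [90.0, 100.0, 110.0]),
        ],
    )
    def test_nearest_multiple_rule(self, wrapped, expected):
        assert unwrap_within_session(np.array(wrapped)).tolist() == expected

    def test_tie_at_180_toward_smaller_absolute_value(self):
        # candidates 190 and -170: the smaller |value| wins
        out = unwrap_within_session(np.array([10.0, 190.0]))
        assert out[1] == -170.0

    @given(
        st.lists(st.floats(-170.0, 170.0), min_size=1, max_size=60),
        st.floats(0.0, 360.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_round_trip_recovers_continuous_ramp(self, steps, start):
        """Any continuous series re-wrapped mod 360 unwraps back exactly
        (up to the branch of the first sample)."""
        truth = start + np.cumsum([0.0] + steps)
        wrapped = truth % 360.0
        out = unwrap_within_session(wrapped)
        shifted = truth - truth[0] + out[0]
        assert np.allclose(out, shifted, atol=1e-9)

    def test_matches_numpy_unwrap_oracle(self, rng):
        truth = np.cumsum(rng.uniform(-170, 170, size=200))
        wrapped = truth % 360.0
        ours = unwrap_within_session(wrapped)
        oracle = np.degrees(np.unwrap(np.radians(wrapped)))
        assert np.allclose(ours - ours[0], oracle - oracle[0], atol=1e-6)


def _band(freqs, phases, levels=None):
    return UnwrappedSeries(
        freqs_hz=np.asarray(freqs, dtype=float),
        phase_deg=np.asarray(phases, dtype=float),
        level_db=None if levels is None else np.asarray(levels, dtype=float),
    )


class TestStitch:
    def test_worked_boundary_example(self):
        """355 deg at 2 kHz then 5 deg at 2.05 kHz: the whole next band
        gains 360 so its first value reads 365."""
        a = _band([1950.0, 2000.0], [350.0, 355.0])
        b = _band([2050.0, 2100.0], [5.0, 12.0])
        out = stitch_sessions([a, b], anchor_freq_hz=1950.0)
        assert out.phase_deg.tolist() == [350.0, 355.0, 365.0, 372.0]

    def test_small_boundary_step_no_shift(self):
        a = _band([1000.0, 1050.0], [100.0, 110.0])
        b = _band([1100.0, 1150.0], [120.0, 130.0])
        out = stitch_sessions([a, b], anchor_freq_hz=1000.0)
        assert out.phase_deg.tolist() == [100.0, 110.0, 120.0, 130.0]

    def test_translation_equivariance(self):
        """Adding 360k to one band's raw data leaves the output unchanged."""
        a = _band([1000.0, 1050.0], [100.0, 170.0])
        b = _band([1100.0, 1150.0], [200.0, 280.0])
        b_shifted = _band([1100.0, 1150.0], [200.0 + 720.0, 280.0 + 720.0])
        out1 = stitch_sessions([a, b], anchor_freq_hz=1000.0)
        out2 = stitch_sessions([a, b_shifted], anchor_freq_hz=1000.0)
        assert np.allclose(out1.phase_deg, out2.phase_deg)

    def test_anchor_kept_in_0_360(self):
        a = _band([250.0, 300.0], [-700.0, -690.0])
        out = stitch_sessions([a])
        assert 0.0 <= out.phase_deg[0] < 360.0

    def test_non_abutting_bands_error(self):
        a = _band([1000.0, 1050.0], [0.0, 0.0])
        b = _band([3000.0, 3050.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="abutting"):
            stitch_sessions([a, b])

    def test_overlapping_bands_error(self):
        a = _band([1000.0, 1100.0], [0.0, 0.0])
        b = _band([1100.0, 1200.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="overlap"):
            stitch_sessions([a, b])

    def test_excluded_anchor_flagged(self):
        a = _band([300.0, 350.0], [10.0, 20.0])
        out = stitch_sessions([a], anchor_freq_hz=250.0)
        assert out.anchor_fallback


class TestProfile:
    def test_identical_series_zero_profile(self):
        s = _band([1000.0, 1050.0], [10.0, 20.0], [1.0, 2.0])
        prof = intercochlear_profile(s, s)
        assert np.all(prof.icpd_deg == 0) and np.all(prof.icld_db == 0)

    def test_common_offset_cancels(self):
        f = [1000.0, 1050.0, 1100.0]
        ipsi = _band(f, [10.0, 30.0, 50.0], [0.0, 1.0, 2.0])
        contra = _band(f, [100.0, 90.0, 80.0], [5.0, 5.0, 5.0])
        base = intercochlear_profile(ipsi, contra)
        off = intercochlear_profile(
            _band(f, ipsi.phase_deg + 77.0, ipsi.level_db + 3.3),
            _band(f, contra.phase_deg + 77.0, contra.level_db + 3.3),
        )
        assert np.allclose(base.icpd_deg, off.icpd_deg)
        assert np.allclose(base.icld_db, off.icld_db)

    def test_mismatched_frequencies_intersect_with_warning(self):
        ipsi = _band([1000.0, 1050.0, 1100.0], [1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        contra = _band([1000.0, 1100.0], [1.0, 1.0], [0.0, 0.0])
        with pytest.warns(UserWarning, match="intersection"):
            prof = intercochlear_profile(ipsi, contra)
        assert prof.freqs_hz.tolist() == [1000.0, 1100.0]

    def test_positive_icld_means_ipsi_greater(self):
        ipsi = _band([1000.0], [0.0], [10.0])
        contra = _band([1000.0], [0.0], [4.0])
        prof = intercochlear_profile(ipsi, contra)
        assert prof.icld_db[0] == pytest.approx(6.0)


def _frame(rows):
    return pd.DataFrame(
        rows,
        columns=["session_id", "freq_hz", "ear", "cancel_level_db",
                 "cancel_phase_deg", "grade", "excluded"],
    )


class TestVariability:
    def test_identical_sessions_zero_sd(self):
        rows = [
            (s, 1000.0, ear, -5.0, 123.0, 4, False)
            for s in range(4)
            for ear in ("ipsi", "contra")
        ]
        summ = session_variability(_frame(rows))
        assert np.allclose(summ.table["sd_level_db"], 0.0)
        assert np.allclose(summ.table["sd_phase_deg"], 0.0)

    def test_wraparound_cell_sd_after_branch_alignment(self):
        """Phases {10, 350} straddle zero; aligned to the circular mean
        they become {10, -10} with sample SD 10*sqrt(2)."""
        rows = [
            (0, 1000.0, "ipsi", 0.0, 10.0, 4, False),
            (1, 1000.0, "ipsi", 0.0, 350.0, 4, False),
        ]
        summ = session_variability(_frame(rows))
        sd = summ.table.loc[summ.table["ear"] == "ipsi", "sd_phase_deg"].iloc[0]
        assert sd == pytest.approx(10.0 * math.sqrt(2.0), rel=1e-9)

    def test_single_session_cell_flagged(self):
        rows = [(0, 1000.0, "ipsi", 0.0, 10.0, 4, False)]
        summ = session_variability(_frame(rows))
        assert summ.table["flagged"].all()
        assert summ.tests == {}


class TestPairedT:
    def test_identical_arrays_degenerate(self):
        res = paired_sd_test(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_sd_test(np.arange(4.0) + 1.0, np.arange(4.0))
        assert res.degenerate and res.p == 0.0 and math.isinf(res.t)

    def test_matches_scipy_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(3, 30)
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            ours = paired_sd_test(a, b)
            t_ref, p_ref = stats.ttest_rel(a, b)
            assert ours.t == pytest.approx(float(t_ref), abs=1e-10)
            assert ours.p == pytest.approx(float(p_ref), abs=1e-10)
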