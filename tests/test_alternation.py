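"""Alternation ratios, circular summaries, Watson-Williams, speed bins."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitasym as g
from gaitasym.alternation import (
    AlternationSeries,
    bin_by_speed,
    circ_summary,
    polar_export,
    spatial_ratios,
    temporal_ratios,
    watson_williams,
)

from conftest import simple_events


def series(ratios, speeds=None, kind="spatial"):
    ratios = np.asarray(ratios, float)
    speeds = np.full_like(ratios, 8.0) if speeds is None else np.asarray(speeds, float)
    return AlternationSeries(kind, "hind", ratios, speeds)


class TestSpatialRatios:
    def _strides(self, limb, rows):
        # rows: (t_start, cycle, stride_length, step_length, velocity)
        return pd.DataFrame(
            [
                {
                    "subject_id": "s1",
                    "condition": "baseline",
                    "trial_id": "t1",
                    "limb": limb,
                    "stride_velocity": v,
                    "stride_length": sl,
                    "step_length": st_,
                    "swing_time": 0.1,
                    "stance_time": 0.4,
                    "cycle_duration": cyc,
                    "t_start": t0,
                    "position": 0.0,
                }
                for t0, cyc, sl, st_, v in rows
            ]
        )

    def test_half_step_gives_symmetric_ratio(self):
        a = self._strides("RH", [(0.3, 0.6, 6.0, 3.0, 10.0)])
        b = self._strides("LH", [(0.0, 0.6, 6.0, np.nan, 10.0)])
        s = spatial_ratios(a, b)
        assert s.ratios[0] == pytest.approx(0.5)
        assert s.speeds[0] == 10.0  # speed of the opposing spanning stride

    def test_third_step(self):
        a = self._strides("RH", [(0.3, 0.6, 6.0, 2.0, 10.0)])
        b = self._strides("LH", [(0.0, 0.6, 6.0, np.nan, 10.0)])
        assert spatial_ratios(a, b).ratios[0] == pytest.approx(1 / 3)

    def test_negative_step_wraps_toward_one(self):
        a = self._strides("RH", [(0.3, 0.6, 6.0, -0.6, 10.0)])
        b = self._strides("LH", [(0.0, 0.6, 6.0, np.nan, 10.0)])
        assert spatial_ratios(a, b).ratios[0] == pytest.approx(0.9)

    def test_zero_opposing_stride_skipped(self):
        a = self._strides("RH", [(0.3, 0.6, 6.0, 3.0, 10.0)])
        b = self._strides("LH", [(0.0, 0.6, 0.0, np.nan, 10.0)])
        s = spatial_ratios(a, b)
        assert len(s) == 0 and s.n_skipped == 1


class TestTemporalRatios:
    def test_mid_cycle_footfall_is_half(self):
        b = simple_events([("LH", 0.0, 0.0, 0.4), ("LH", 6.0, 0.6, 1.0)])
        a = simple_events([("RH", 3.0, 0.3, 0.7)])
        s = temporal_ratios(a, b)
        assert s.ratios[0] == pytest.approx(0.5)
        assert s.speeds[0] == pytest.approx(10.0)

    def test_quarter_cycle_offset(self):
        b = simple_events([("LH", 0.0, 0.0, 0.4), ("LH", 6.0, 0.6, 1.0)])
        a = simple_events([("RH", 1.5, 0.15, 0.55)])
        assert temporal_ratios(a, b).ratios[0] == pytest.approx(0.25)

    def test_cycle_with_two_opposing_footfalls_skipped(self):
        b = simple_events([("LH", 0.0, 0.0, 0.4), ("LH", 6.0, 0.6, 1.0)])
        a = simple_events([("RH", 1.0, 0.1, 0.5), ("RH", 3.0, 0.3, 0.7)])
        s = temporal_ratios(a, b)
        assert len(s) == 0 and s.n_skipped == 1

    def test_simulator_phase_offset_recovered(self):
        prof = g.GaitProfile.mouse().noiseless()
        import dataclasses

        prof = dataclasses.replace(prof, phase_offset=0.4)
        ev = g.generate_trial(prof, 30, seed=5)
        s = temporal_ratios(ev[ev.limb == "RH"], ev[ev.limb == "LH"])
        assert circ_summary(s).mean_ratio == pytest.approx(0.4, abs=1e-9)


class TestCircSummary:
    def test_concentrated_ratios(self):
        s = circ_summary(series([0.5, 0.5, 0.5]))
        assert s.mean_ratio == pytest.approx(0.5) and s.r == pytest.approx(1.0)

    def test_antipodal_cancellation_flagged(self):
        s = circ_summary(series([0.0, 0.5]))
        assert s.r == pytest.approx(0.0, abs=1e-12) and s.undefined

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        ratios = np.mod(0.5 + 0.1 * rng.standard_normal(200), 1)
        theta = 2 * np.pi * ratios
        s = circ_summary(series(ratios))
        assert s.r == pytest.approx(float(pg.circ_r(theta)), abs=1e-12)
        assert s.mean_direction == pytest.approx(
            float(pg.circ_mean(theta)) % (2 * np.pi), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        delta=st.floats(0, 1, exclude_max=True),
        seed=st.integers(0, 100),
    )
    def test_rotation_equivariance(self, delta, seed):
        rng = np.random.default_rng(seed)
        ratios = np.mod(0.5 + 0.05 * rng.standard_normal(30), 1)
        a = circ_summary(series(ratios))
        b = circ_summary(series(np.mod(ratios + delta, 1)))
        assert b.r == pytest.approx(a.r, abs=1e-9)
        diff = (b.mean_ratio - a.mean_ratio - delta) % 1.0
        assert min(diff, 1 - diff) < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 100))
    def test_reflection_maps_mean_and_preserves_r(self, seed):
        rng = np.random.default_rng(seed)
        ratios = np.mod(0.3 + 0.05 * rng.standard_normal(30), 1)
        a = circ_summary(series(ratios))
        b = circ_summary(series(np.mod(1 - ratios, 1)))
        assert b.r == pytest.approx(a.r, abs=1e-9)
        diff = (a.mean_ratio + b.mean_ratio) % 1.0
        assert min(diff, 1 - diff) < 1e-9


class TestWatsonWilliams:
    def test_identical_samples_give_f_zero(self):
        a = series(np.mod(0.5 + 0.05 * np.random.default_rng(2).standard_normal(40), 1))
        res = watson_williams(a, a)
        assert res.F == pytest.approx(0.0, abs=1e-9) and res.p == pytest.approx(1.0)

    def test_separated_concentrated_samples_detected(self):
        rng = np.random.default_rng(3)
        a = series(np.mod(0.50 + 0.03 * rng.standard_normal(50), 1))
        b = series(np.mod(0.40 + 0.03 * rng.standard_normal(50), 1))
        assert watson_williams(a, b).p < 0.05

    def test_invariant_under_common_rotation(self):
        rng = np.random.default_rng(4)
        a = np.mod(0.5 + 0.05 * rng.standard_normal(50), 1)
        b = np.mod(0.45 + 0.05 * rng.standard_normal(50), 1)
        r1 = watson_williams(series(a), series(b))
        r2 = watson_williams(series(np.mod(a + 0.3, 1)), series(np.mod(b + 0.3, 1)))
        assert r2.F == pytest.approx(r1.F, rel=1e-9)

    def test_low_concentration_warned(self):
        rng = np.random.default_rng(5)
        a = series(rng.uniform(0, 1, 50) * 0.98)
        b = series(rng.uniform(0, 1, 50) * 0.98)
        res = watson_williams(a, b)
        assert any("0.45" in w for w in res.warnings)

class TestBinBySpeed:
    def test_one_ratio_per_bin(self):
        s = series([0.5, 0.5], speeds=[5.0, 12.0])
        bins = bin_by_speed(s)
        assert len(bins[0][1]) == 1 and len(bins[1][1]) == 1

    def test_boundary_speed_goes_to_upper_bin(self):
        s = series([0.5], speeds=[10.0])
        bins = bin_by_speed(s)
        assert len(bins[0][1]) == 0 and len(bins[1][1]) == 1

    def test_upper_edge_of_last_bin_included(self):
        s = series([0.5], speeds=[16.0])
        assert len(bin_by_speed(s)[1][1]) == 1

    def test_empty_bin_reported_not_fatal(self):
        s = series([0.5], speeds=[5.0])
        bins = bin_by_speed(s)
        assert len(bins[1][1]) == 0


class TestPolarExport:
    def test_summary_row_geometry(self):
        summ = circ_summary(series([0.5, 0.5]))
        tab = polar_export({"baseline": summ})
        row = tab.iloc[0]
        assert row["angle_rad"] == pytest.approx(math.pi)
        assert row["radius"] == pytest.approx(1.0)

    def test_empty_raw_set_gives_header_only(self):
        tab = polar_export({}, raw={})
        assert len(tab) == 0 and "angle_rad" in tab.columns

    def test_round_trip_reproduces_summaries(self, tmp_path):
        rng = np.random.default_rng(8)
        ratios = np.mod(0.5 + 0.05 * rng.standard_normal(50), 1)
        summ = circ_summary(series(ratios))
        tab = polar_export({"a": summ}, raw={"a": ratios})
        path = tmp_path / "polar.csv"
        tab.to_csv(path, index=False)
        back = pd.read_csv(path, float_precision="round_trip")
        srow = back[back["type"] == "summary"].iloc[0]
        assert srow["angle_rad"] == summ.mean_direction
        assert srow["radius"] == summ.r
        raw_back = back[back["type"] == "raw"]["ratio"].to_numpy()
        re_summ = circ_summary(series(raw_back))
        assert re_summ.mean_direction == pytest.approx(summ.mean_direction, abs=1e-12)
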