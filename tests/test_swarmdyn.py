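import math

import numpy as np
import pandas as pd
import pytest

from beelek import swarmdyn
from beelek.flightseg import CONVOLUTED, FlightSection
from beelek.lekfind import Congregation
from beelek.swarmdyn import (
    binned_profile,
    detect_visits,
    fit_well,
    gaussian_core_points,
    kinematics,
    kurtosis,
    location_summary,
)
from beelek.trackio import HiveRecord

from conftest import make_segment


def _section_for(seg, label=CONVOLUTED):
    xy = seg.xy
    com = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
    return FlightSection(seg.segment_id, label, 0, len(seg), com, seg.duration_s, 1.0)


def _area(center, area_id="A"):
    return Congregation(
        area_id=area_id,
        center=center,
        hull=np.array([[center[0] - 1, center[1] - 1], [center[0] + 1, center[1] - 1],
                       [center[0], center[1] + 1]]),
        members=pd.DataFrame(columns=["segment_id", "fix_index", "x", "y"]),
        n_segments=10,
    )


class TestKinematics:
    def test_finite_differences(self):
        seg = make_segment([0, 3, 6], [0, 3, 9], [0, 0, 0])
        df = kinematics(seg, _section_for(seg), center=(0.0, 0.0))
        assert len(df) == 1
        assert df.vx.iloc[0] == pytest.approx(1.0)  # incoming transition
        assert df.ax.iloc[0] == pytest.approx((2.0 - 1.0) / 3.0)
        assert df.x_rel.iloc[0] == pytest.approx(3.0)  # sample at shared fix

    def test_uniform_motion_zero_acceleration(self):
        t = 3.0 * np.arange(10)
        seg = make_segment(t, 4.0 * t, -2.0 * t)
        df = kinematics(seg, _section_for(seg), center=(0.0, 0.0))
        np.testing.assert_allclose(df.ax, 0.0, atol=1e-12)
        np.testing.assert_allclose(df.ay, 0.0, atol=1e-12)

    def test_center_translation(self):
        t = 3.0 * np.arange(8)
        seg = make_segment(t, np.sin(t), np.cos(t))
        a = kinematics(seg, _section_for(seg), center=(0.0, 0.0))
        b = kinematics(seg, _section_for(seg), center=(5.0, 0.0))
        np.testing.assert_allclose(b.x_rel, a.x_rel - 5.0)
        np.testing.assert_allclose(b.vx, a.vx)
        np.testing.assert_allclose(b.ax, a.ax)

    def test_too_few_fixes(self):
        seg = make_segment([0, 3], [0, 1], [0, 1])
        assert kinematics(seg, _section_for(seg), (0, 0)).empty

    def test_mean_dt_mode(self):
        seg = make_segment([0, 3, 9], [0, 3, 15], [0, 0, 0])
        trailing = kinematics(seg, _section_for(seg), (0, 0), dt_mode="trailing")
        mean = kinematics(seg, _section_for(seg), (0, 0), dt_mode="mean")
        # dv = 1 m/s; trailing interval 6 s, mean interval 4.5 s
        assert trailing.ax.iloc[0] == pytest.approx(1.0 / 6.0)
        assert mean.ax.iloc[0] == pytest.approx(1.0 / 4.5)


def _samples(pairs, axis="x"):
    return pd.DataFrame(
        {
            "x_rel": [p[0] for p in pairs],
            "y_rel": 0.0,
            "ax": [p[1] for p in pairs],
            "ay": 0.0,
            "vx": 0.0,
            "vy": 0.0,
            "t": np.arange(len(pairs), dtype=float),
            "segment_id": "s",
            "location_id": "A",
        }
    )


class TestFitWell:
    def test_exact_line_through_origin(self):
        fit = fit_well(_samples([(-10, 1), (0, 0), (10, -1)]), "x")
        assert fit.slope == pytest.approx(-0.1)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.x_intercept == pytest.approx(0.0, abs=1e-9)

    def test_exact_offset_line(self):
        fit = fit_well(_samples([(0, 0.5), (10, -0.5), (5, 0)]), "x")
        assert fit.slope == pytest.approx(-0.1)
        assert fit.intercept == pytest.approx(0.5)
        assert fit.x_intercept == pytest.approx(5.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_well(_samples([(0, 0.5), (10, -0.5)]), "x")

    def test_degenerate_position(self):
        with pytest.raises(ValueError):
            fit_well(_samples([(1, 0), (1, 1), (1, 2)]), "x")

    def test_recovers_planted_well(self):
        # OU well: regression of acceleration on position estimates -k and
        # the x-intercept locates the planted center
        from beelek.simulate import simulate_swarm_bout

        rng = np.random.default_rng(11)
        k, gamma, sigma = 0.05, 0.5, 1.0
        center = (30.0, -20.0)
        xy = simulate_swarm_bout(center, k, gamma, sigma, 2000.0, 0.1, rng)
        t = 0.1 * np.arange(len(xy))
        seg = make_segment(t, xy[:, 0], xy[:, 1], segment_id="ou")
        df = kinematics(seg, _section_for(seg), center=(0.0, 0.0))
        for axis, c in (("x", center[0]), ("y", center[1])):
            fit = fit_well(df, axis)
            assert abs(fit.slope + k) < 2 * fit.slope_se + 0.1 * k
            xint_se = abs(fit.x_intercept) * math.sqrt(
                (fit.intercept_se / fit.intercept) ** 2 + (fit.slope_se / fit.slope) ** 2
            )
            assert abs(fit.x_intercept - c) < max(2 * xint_se, 0.1 * abs(c))


class TestBinnedProfile:
    def test_bin_statistics(self):
        prof = binned_profile(_samples([(-7.0, 1.0), (-6.0, 3.0)]), "x")
        b = np.searchsorted(prof.bin_edges, -7.0, side="right") - 1
        assert prof.bin_edges[b] == -10.0
        assert prof.mean_accel[b] == pytest.approx(2.0)
        assert prof.se[b] == pytest.approx(1.0)
        assert prof.n[b] == 2

    def test_empty_bins_flagged(self):
        prof = binned_profile(_samples([(-7.0, 1.0), (-6.0, 3.0)]), "x")
        assert prof.empty_bins.sum() == len(prof.n) - 1
        assert np.isnan(prof.mean_accel[prof.empty_bins]).all()

    def test_linear_data_means_on_regression_line(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-45, 45, 400)
        pairs = list(zip(x, -0.05 * x + 0.2))
        df = _samples(pairs)
        fit = fit_well(df, "x")
        prof = binned_profile(df, "x")
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        ok = ~prof.empty_bins
        np.testing.assert_allclose(
            prof.mean_accel[ok], fit.intercept + fit.slope * centers[ok], atol=0.08
        )


class TestKurtosis:
    def test_direct_moment_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            v = rng.normal(size=50) ** 3
            m2 = np.mean((v - v.mean()) ** 2)
            m4 = np.mean((v - v.mean()) ** 4)
            assert kurtosis(v) == pytest.approx(m4 / m2**2, abs=1e-12)

    def test_two_point_distribution(self):
        assert kurtosis([-1.0, 1.0] * 10) == pytest.approx(1.0)

    def test_uniform(self):
        rng = np.random.default_rng(0)
        assert kurtosis(rng.uniform(size=100_000)) == pytest.approx(1.8, abs=0.05)

    def test_gaussian(self):
        rng = np.random.default_rng(0)
        assert kurtosis(rng.normal(size=100_000)) == pytest.approx(3.0, abs=0.08)

    def test_errors(self):
        with pytest.raises(ValueError):
            kurtosis([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            kurtosis([2.0] * 10)


class TestGaussianCorePoints:
    def test_gaussian_on_identity(self):
        rng = np.random.default_rng(4)
        pts = gaussian_core_points(rng.normal(3.0, 2.0, 5000))
        core = np.abs(pts[:, 0]) < 2.0
        assert np.max(np.abs(pts[core, 0] - pts[core, 1])) < 0.15

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=500)
        a = gaussian_core_points(v)
        b = gaussian_core_points(7.0 * v - 3.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_heavy_tail_departure(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(size=9000), rng.normal(0, 5, 1000)])
        pts = gaussian_core_points(v)
        # upper tail of a leptokurtic sample lies above the identity line
        assert pts[-20:, 1].mean() > pts[-20:, 0].mean() + 0.5

    def test_min_n(self):
        with pytest.raises(ValueError):
            gaussian_core_points(np.arange(5.0))


class TestDetectVisits:
    def _segment_through(self, center, dwell_fixes, far_start=True):
        """Segment passing into the 50 m disc of `center`."""
        xs, ys, ts = [], [], []
        t = 0.0
        if far_start:
            for i in range(5):
                ts.append(t)
                xs.append(center[0] - 200 + 14 * i)
                ys.append(center[1])
                t += 3.0
        for i in range(dwell_fixes):
            ts.append(t)
            xs.append(center[0] + 5 * math.sin(i))
            ys.append(center[1] + 5 * math.cos(i))
            t += 3.0
        for i in range(5):
            ts.append(t)
            xs.append(center[0] + 80 + 14 * i)
            ys.append(center[1])
            t += 3.0
        return make_segment(ts, xs, ys, segment_id="v")

    def test_pass_through_too_short(self):
        area = _area((0.0, 0.0))
        seg = self._segment_through((0.0, 0.0), dwell_fixes=3)  # 9 s inside (runs 0,3,6)
        visits = detect_visits(seg, [], [area])
        assert [v for v in visits if v.basis == "dwell"] == []

    def test_dwell_visit(self):
        area = _area((0.0, 0.0))
        seg = self._segment_through((0.0, 0.0), dwell_fixes=9)  # 24 s inside
        visits = detect_visits(seg, [], [area])
        assert any(v.basis == "dwell" and v.area_id == "A" for v in visits)

    def test_convoluted_com_basis(self):
        area = _area((0.0, 0.0))
        seg = make_segment([0, 3, 6, 9], [45, 46, 45, 44], [0, 1, -1, 0], segment_id="c")
        sec = FlightSection("c", CONVOLUTED, 0, 4, (45.0, 0.0), 9.0, 1.0)
        visits = detect_visits(seg, [sec], [area])
        assert [v.basis for v in visits if v.area_id == "A"] == ["convoluted_com"]

    def test_gap_bridging(self):
        area = _area((0.0, 0.0))
        # inside at t=0, signal lost, inside again at t=60: dwell bridged
        seg = make_segment([0.0, 60.0, 63.0], [10.0, -10.0, 100.0], [0.0, 0.0, 0.0], segment_id="g")
        visits = detect_visits(seg, [], [area])
        assert any(v.basis == "dwell" and v.t_end - v.t_start >= 21.0 for v in visits)

    def test_dwell_threshold_monotonicity(self):
        area = _area((0.0, 0.0))
        seg = self._segment_through((0.0, 0.0), dwell_fixes=12)
        counts = [
            len(detect_visits(seg, [], [area], dwell_s=d)) for d in (9.0, 21.0, 40.0, 90.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestLocationSummary:
    def test_mean_duration_per_location(self):
        area = _area((0.0, 0.0))
        rows = []
        for sid, dur in (("a", 60.0), ("b", 120.0)):
            t = np.arange(0.0, dur + 1, 3.0)
            seg = make_segment(t, 5 * np.sin(t), 5 * np.cos(t), segment_id=sid)
            sec = FlightSection(sid, CONVOLUTED, 0, len(seg), (0.0, 0.0), dur, 2.0)
            rows.append((seg, [sec]))
        sections_df, locations_df, samples = location_summary(rows, [area], [])
        assert locations_df.mean_duration_s.iloc[0] == pytest.approx(90.0)
        assert set(sections_df.location_id) == {"A"}

    def test_tie_goes_to_nearer_center(self):
        area = _area((0.0, 0.0))
        hive = HiveRecord("1", (60.0, 0.0))
        sec = FlightSection("s", CONVOLUTED, 0, 4, (20.0, 0.0), 30.0, 2.0)
        loc_id, kind, _ = swarmdyn.assign_section_location(sec, [area], [hive])
        assert (loc_id, kind) == ("A", "congregation")
        sec2 = FlightSection("s", CONVOLUTED, 0, 4, (45.0, 0.0), 30.0, 2.0)
        loc_id2, kind2, _ = swarmdyn.assign_section_location(sec2, [area], [hive])
        assert (loc_id2, kind2) == ("1", "hive")

    def test_equidistant_prefers_congregation(self):
        area = _area((0.0, 0.0))
        hive = HiveRecord("1", (60.0, 0.0))
        sec = FlightSection("s", CONVOLUTED, 0, 4, (30.0, 0.0), 30.0, 2.0)
        loc_id, kind, _ = swarmdyn.assign_section_location(sec, [area], [hive])
        assert kind == "congregation"

    def test_hive_vs_congregation_contrast(self, sim_pipeline):
        # simulated hive hover is slow/heavy-tailed; swarms are fast/Gaussian
        stats = sim_pipeline.location_stats
        hives = stats[stats.location_kind == "hive"]
        areas = stats[stats.location_kind == "congregation"]
        assert hives.kurt_x.mean() > areas.kurt_x.mean()
        assert hives.kurt_y.mean() > areas.kurt_y.mean()
        assert hives.mean_speed_ms.mean() < areas.mean_speed_ms.mean()
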