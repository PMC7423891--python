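"""Kinetics analysis: length traces, rates, interruptions, end morphology,
and the composition-dependence fits."""

import numpy as np
import pytest

from mtwedge import fixtures, kinetics
from mtwedge.kinetics import (
    LengthTrace, RateCurve, RateSeries, calibrate_time, detect_interruptions,
    instantaneous_rate, intact_row_count, local_uncompressed_count,
    percent_time_interrupted_curve, rate_vs_composition)


class TestLengthTrace:
    def test_intact_lattice_full_length(self, params):
        state = fixtures.make_fixture("intact_8row")
        traj = kinetics._as_single_frame(state)
        assert intact_row_count(traj, 0) == 8

    def test_forty_row_length_in_um(self, params):
        # 40 intact rows at 9 nm per row = 0.36 um
        assert 40 * params.nm_per_row / 1000.0 == pytest.approx(0.36)

    def test_displaced_top_rows_shorten_length(self):
        state = fixtures.make_fixture("intact_8row")
        state.pos[state.meta["row"] >= 5] += 50.0
        traj = kinetics._as_single_frame(state)
        assert intact_row_count(traj, 0) == 5

    def test_peeled_protofilament_defines_front(self):
        state = fixtures.make_fixture("peeled_pf")
        traj = kinetics._as_single_frame(state)
        assert intact_row_count(traj, 0) == 5

    def test_delta_is_loss_since_start(self):
        tr = fixtures.linear_trace(rate_um_s=0.1, duration_s=50)
        assert np.allclose(tr.delta_um, tr.length_um[0] - tr.length_um)
        assert (tr.delta_um >= 0).all()

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            LengthTrace(times=[0.0, 1.0, 1.0], length_um=[3, 2, 1])


class TestInstantaneousRate:
    def test_linear_trace_constant_rate(self):
        tr = fixtures.linear_trace(rate_um_s=0.24)
        rs = instantaneous_rate(tr, window=10.0)
        assert np.allclose(rs.rate, 0.24)

    def test_constant_trace_zero_rate(self):
        tr = LengthTrace(times=np.arange(0, 100, 5.0),
                         length_um=np.full(20, 12.0))
        rs = instantaneous_rate(tr, window=10.0)
        assert np.allclose(rs.rate, 0.0)

    def test_piecewise_segments_recovered(self):
        tr = fixtures.piecewise_trace([(30, 0.24), (20, 0.0), (30, 0.24)])
        rs = instantaneous_rate(tr, window=2.0)
        # away from the breakpoints the rate matches each segment
        fast_early = rs.rate[(rs.times > 2) & (rs.times < 28)]
        flat = rs.rate[(rs.times > 32) & (rs.times < 48)]
        fast_late = rs.rate[(rs.times > 52) & (rs.times < 78)]
        assert np.allclose(fast_early, 0.24)
        assert np.allclose(flat, 0.0)
        assert np.allclose(fast_late, 0.24)

    def test_window_validation(self):
        tr = fixtures.linear_trace(duration_s=30)
        with pytest.raises(ValueError):
            instantaneous_rate(tr, window=1000.0)
        with pytest.raises(ValueError):
            instantaneous_rate(tr, window=1.0)  # below 2 sample intervals


class TestInterruptions:
    @staticmethod
    def _series(flats, dt=0.5, rate=0.2):
        """Rate series with exact near-zero stretches [(start, end), ...]."""
        t = np.arange(0.0, 120.0, dt)
        r = np.full_like(t, rate)
        for a, b in flats:
            r[(t >= a) & (t <= b)] = 0.0
        return RateSeries(times=t, rate=r)

    def test_steady_loss_no_interruptions(self):
        rs = self._series([])
        ana = detect_interruptions(rs, rate_threshold=0.02, min_duration=2.0)
        assert ana.records == []
        assert ana.percent_time_interrupted == 0.0

    def test_single_flat_segment(self):
        rs = self._series([(40.0, 50.0)])
        ana = detect_interruptions(rs, rate_threshold=0.02, min_duration=2.0)
        assert len(ana.records) == 1
        assert ana.records[0].duration == pytest.approx(10.0)

    def test_three_segments_mean_duration(self):
        rs = self._series([(10.0, 15.0), (30.0, 38.0), (60.0, 72.0)])
        ana = detect_interruptions(rs, rate_threshold=0.02, min_duration=2.0,
                                   total_loss_um=10.0)
        assert [r.duration for r in ana.records] == \
            pytest.approx([5.0, 8.0, 12.0])
        assert ana.mean_duration_s == pytest.approx(25.0 / 3)
        assert ana.interruptions_per_um == pytest.approx(0.3)

    def test_durations_below_minimum_ignored(self):
        rs = self._series([(10.0, 11.0)])
        ana = detect_interruptions(rs, rate_threshold=0.02, min_duration=5.0)
        assert ana.records == []

    def test_percent_time_bounded(self):
        rs = self._series([(0.0, 119.5)])
        ana = detect_interruptions(rs, rate_threshold=0.02, min_duration=2.0)
        assert 0.0 <= ana.percent_time_interrupted <= 100.0


class TestPercentTimeCurve:
    def test_exact_recovery_of_linear_law(self):
        groups = {x: [115.4 * x - 22.1] for x in (0.3, 0.5, 0.7, 0.9)}
        fit = percent_time_interrupted_curve(groups)
        assert fit.slope == pytest.approx(115.4)
        assert fit.intercept == pytest.approx(-22.1)
        assert fit.r_squared == pytest.approx(1.0)
        # onset near 19% uncompressed
        assert fit.x_intercept == pytest.approx(22.1 / 115.4)

    def test_constant_response(self):
        fit = percent_time_interrupted_curve({0.2: [5.0], 0.5: [5.0], 0.8: [5.0]})
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            percent_time_interrupted_curve({0.2: [1.0], 0.4: [2.0]})

    def test_noisy_recovery_within_two_se(self):
        """Linear fit recovers generating parameters under 10% noise."""
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(100):
            xs = np.linspace(0.3, 1.0, 6)
            ys = 115.4 * xs - 22.1
            ys = ys * (1 + 0.1 * rng.standard_normal(6))
            fit = percent_time_interrupted_curve(
                {x: [y] for x, y in zip(xs, ys)})
            slopes.append(fit.slope)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / 10
        assert abs(slopes.mean() - 115.4) < 2 * se + 1e-9


class TestEndMorphology:
    def test_intact_lattice_all_zero_exposure(self):
        state = fixtures.make_fixture("intact_8row")
        assert kinetics.exposed_protofilament_lengths(state).tolist() == [0] * 13

    def test_single_peeled_horn(self):
        state = fixtures.make_fixture("peeled_pf")
        lengths = kinetics.exposed_protofilament_lengths(state)
        assert lengths[4] == 15
        assert lengths.sum() == 15

    def test_local_composition_window(self):
        state = fixtures.make_fixture("intact_8row")
        grid = state.config.composition
        res = local_uncompressed_count(state)
        assert res.rows_used == 3 and not res.partial
        assert res.count == int(grid[5:8].sum())

    def test_local_composition_extremes(self, params):
        from mtwedge.lattice import LatticeConfiguration, build_microtubule
        for frac, expected in ((1.0, 39), (0.0, 0)):
            cfg = LatticeConfiguration.uniform(6, frac)
            state = build_microtubule(cfg, params)
            state.reference = {"pos": state.pos.copy(),
                               "quat": state.quat.copy()}
            assert local_uncompressed_count(state).count == expected


class TestRateVsComposition:
    def test_exact_recovery_noiseless(self):
        x, y = fixtures.exponential_rate_points(a=0.60, b=0.060)
        curve = RateCurve(np.concatenate([[0.0, 5.0], x]),
                          np.concatenate([[0.24, 0.24], y]),
                          np.zeros(len(x) + 2), np.full(len(x) + 2, 5))
        fit = rate_vs_composition(curve)
        assert fit.prefactor == pytest.approx(0.60, rel=1e-6)
        assert fit.decay == pytest.approx(0.060, rel=1e-6)
        assert fit.plateau == pytest.approx(0.24)
        # slowdown onset where the decay branch meets the plateau
        assert fit.crossing == pytest.approx(np.log(0.60 / 0.24) / 0.060)
        assert 15.0 < fit.crossing < 20.0

    def test_sixty_percent_reduction_at_thirty(self):
        rel = 0.60 * np.exp(-0.060 * 30) / 0.240
        assert 1 - rel == pytest.approx(0.587, abs=1e-3)

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(1)
        decays = []
        for _ in range(100):
            x, y = fixtures.exponential_rate_points(
                x=(20, 35, 50, 65, 80, 100), noise_frac=0.1, rng=rng)
            curve = RateCurve(np.concatenate([[0.0], x]),
                              np.concatenate([[0.24], y]),
                              np.zeros(len(x) + 1), np.ones(len(x) + 1))
            decays.append(rate_vs_composition(curve).decay)
        decays = np.array(decays)
        se = decays.std(ddof=1) / 10
        assert abs(decays.mean() - 0.060) < 2 * se + 1e-12


class TestCalibrateTime:
    def test_reference_matching(self):
        assert calibrate_time(0.24 / 3e6) == pytest.approx(3e6)

    def test_identity_and_linearity(self):
        assert calibrate_time(0.5, 0.5) == 1.0
        assert calibrate_time(0.5, 1.0) == 2 * calibrate_time(0.5, 0.5)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            calibrate_time(0.0)
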