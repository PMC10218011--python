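import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from blockbold import (
    BoldRun, NoiseSpec, circular_mean_sd, compare_groups, extract_timecourse,
    mean_response, period_average, simulate_block_run, spectral_summary,
    split_periods, wrap_deg,
)
from blockbold.core import Roi
from blockbold.motion import ScreenResult
from blockbold.spectral import PeriodAverage, RoiTimecourse, _boxcar_phase_rad


def _run_from_matrix(mat, schedule):
    """(n_t, n_vox) matrix -> BoldRun on an (n_vox, 1, 1) grid, no dummies."""
    data = mat.T.reshape(mat.shape[1], 1, 1, mat.shape[0])
    return BoldRun(data, schedule.tr_s, 0, 3.0, schedule)


def _roi(n_vox, grid):
    return Roi("roi", "L", np.array([[i, 0, 0] for i in range(n_vox)]), grid)


class TestExtractTimecourse:
    def test_constant_run_gives_zero_percent(self, schedule):
        run = _run_from_matrix(np.full((84, 3), 500.0), schedule)
        tc = extract_timecourse(run, _roi(3, (3, 1, 1)))
        assert np.allclose(tc.values, 0.0)

    def test_single_voxel_modulation_recovered(self, schedule, hrf):
        reg = hrf.convolve(schedule.boxcar())
        reg = reg - reg.mean()
        mat = 1000.0 * (1 + 0.01 * reg)[:, None]
        run = _run_from_matrix(mat, schedule)
        tc = extract_timecourse(run, _roi(1, (1, 1, 1)))
        assert np.allclose(tc.values, reg, atol=1e-9)

    def test_mixed_amplitudes_average_linearly(self, schedule, hrf):
        """Equal mix of 0.4% and 0.8% voxels reads 0.6%."""
        reg = hrf.convolve(schedule.boxcar())
        reg = reg - reg.mean()
        mat = np.column_stack([1000 * (1 + 0.004 * reg),
                               1000 * (1 + 0.008 * reg)])
        run = _run_from_matrix(mat, schedule)
        tc = extract_timecourse(run, _roi(2, (2, 1, 1)))
        assert np.allclose(tc.values, 0.6 * reg, atol=1e-9)

    def test_empty_roi_rejected(self, schedule):
        run = _run_from_matrix(np.full((84, 2), 1.0), schedule)
        with pytest.raises(ValueError):
            Roi("x", "L", np.empty((0, 3)), (2, 1, 1))


class TestSplitPeriods:
    def test_fully_retained_run_has_six_good_periods(self, schedule):
        tc = RoiTimecourse(np.arange(84.0), schedule)
        periods, good = split_periods(tc)
        assert periods.shape == (6, 14)
        assert good == [0, 1, 2, 3, 4, 5]

    def test_burst_spanning_one_period_drops_it(self, schedule):
        tc = RoiTimecourse(np.arange(84.0), schedule)
        screen = ScreenResult("segment", [(0, 40), (42, 84)], "burst")
        _, good = split_periods(tc, screen)
        assert good == [0, 1, 3, 4, 5]  # period 2 (TRs 28..41) straddles 40

    def test_partial_retention_keeps_full_periods_only(self, schedule):
        tc = RoiTimecourse(np.arange(84.0), schedule)
        screen = ScreenResult("segment", [(0, 49)], "tail motion")  # 3.5 periods
        _, good = split_periods(tc, screen)
        assert good == [0, 1, 2]

    def test_no_good_period_raises(self, schedule):
        tc = RoiTimecourse(np.arange(84.0), schedule)
        screen = ScreenResult("segment", [(2, 15)], "everything moved")
        with pytest.raises(ValueError, match="period"):
            split_periods(tc, screen)


class TestPeriodAverage:
    def test_identical_periods_have_zero_sd(self):
        periods = np.tile(np.arange(14.0), (6, 1))
        pa = period_average(periods)
        assert np.allclose(pa.sd, 0.0)
        assert pa.n_periods == 6

    def test_two_periods_average_pointwise(self):
        pa = period_average(np.array([[1.0] * 14, [3.0] * 14]))
        assert np.allclose(pa.mean, 2.0)

    def test_sd_shrinks_with_period_count(self, schedule):
        """Across-period SD of the mean scales as 1/sqrt(n)."""
        rng = np.random.default_rng(0)
        sems = []
        for n in (2, 8, 32):
            reps = [period_average(rng.normal(0, 1, (n, 14))).mean.std()
                    for _ in range(200)]
            sems.append(np.mean(reps))
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.2)
        assert sems[1] / sems[2] == pytest.approx(2.0, rel=0.2)


class TestMeanResponse:
    def test_flat_period_returns_level(self):
        pa = PeriodAverage(np.full(14, 1.0), np.zeros(14), 6)
        assert mean_response(pa) == 1.0

    def test_ramp_pins_one_based_inclusive_window(self):
        """TRs 3..6 of the ramp 0..13 average to (2+3+4+5)/4 = 3.5."""
        pa = PeriodAverage(np.arange(14.0), np.zeros(14), 6)
        assert mean_response(pa) == 3.5

    def test_noiseless_simulation_matches_closed_form(self, scene, schedule,
                                                      hrf, noiseless):
        run, trace, truth = simulate_block_run(scene, schedule, noise=noiseless)
        roi = scene.true_rois()["MT+ L"]
        tc = extract_timecourse(run, roi)
        pa = period_average(*split_periods(tc))
        expected = 0.4 * truth.regressor.reshape(6, 14).mean(axis=0)[2:6].mean()
        assert mean_response(pa) == pytest.approx(expected, abs=1e-9)

    def test_window_outside_period_rejected(self):
        pa = PeriodAverage(np.arange(14.0), np.zeros(14), 6)
        with pytest.raises(ValueError):
            mean_response(pa, window=(10, 20))


class TestSpectralSummary:
    def test_boxcar_itself_reads_zero_phase(self, schedule):
        tc = RoiTimecourse(schedule.boxcar(), schedule)
        s = spectral_summary(tc)
        assert s.phase_deg == pytest.approx(0.0, abs=1e-9)
        assert s.snr > 10

    def test_aligned_cosine_reads_zero_phase_and_high_snr(self):
        n_p, p_tr = 6, 14
        t = np.arange(n_p * p_tr)
        ref = _boxcar_phase_rad(n_p, p_tr)
        series = np.cos(2 * np.pi * n_p * t / len(t) + ref)
        series += np.random.default_rng(0).normal(0, 1e-4, len(t))
        s = spectral_summary(series, n_p, p_tr)
        assert s.snr > 100
        assert abs(wrap_deg(s.phase_deg)) < 1.0
        assert s.p < 0.01

    def test_canonical_response_reads_64_degrees(self, schedule, hrf):
        reg = hrf.convolve(schedule.boxcar())
        s = spectral_summary(RoiTimecourse(reg, schedule))
        assert s.phase_deg == pytest.approx(64.0, abs=3.0)

    def test_white_noise_snr_matches_null_oracle(self):
        """Median SNR of pure-noise series equals the closed-form null in
        which all three bins are iid complex Gaussians."""
        rng = np.random.default_rng(42)
        snrs = [spectral_summary(rng.normal(0, 1, 84), 6, 14).snr
                for _ in range(1000)]
        # independent oracle: three iid complex-normal bins
        a = rng.normal(0, 1, (3, 20000)) + 1j * rng.normal(0, 1, (3, 20000))
        oracle = np.abs(a[0]) / np.sqrt((np.abs(a[1]) ** 2 + np.abs(a[2]) ** 2) / 2)
        assert np.median(snrs) == pytest.approx(np.median(oracle), abs=0.08)

    def test_null_significance_uniform(self):
        rng = np.random.default_rng(7)
        ps = [spectral_summary(rng.normal(0, 1, 84), 6, 14).p
              for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_phase_equivariant_under_delay(self, schedule, hrf):
        """Delaying the series by k TRs adds k*360/14 degrees of phase."""
        reg = hrf.convolve(schedule.boxcar())
        base = spectral_summary(RoiTimecourse(reg, schedule)).phase_deg
        for k in (1, 3):
            rolled = spectral_summary(RoiTimecourse(np.roll(reg, k), schedule))
            expected = (base + k * 360.0 / 14.0) % 360.0
            assert rolled.phase_deg == pytest.approx(expected, abs=1e-6)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_snr_invariant_to_rescaling(self, scale):
        rng = np.random.default_rng(3)
        series = rng.normal(0, 1, 84) + np.cos(2 * np.pi * 6 * np.arange(84) / 84)
        a = spectral_summary(series, 6, 14)
        b = spectral_summary(series * scale, 6, 14)
        assert b.snr == pytest.approx(a.snr, rel=1e-9)
        assert b.phase_deg == pytest.approx(a.phase_deg, abs=1e-9)

    def test_parseval_power_identity(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 84)
        x -= x.mean()
        spec = np.fft.fft(x)
        assert np.sum(np.abs(spec) ** 2) / len(x) == pytest.approx(
            np.sum(x ** 2), rel=1e-12)

    def test_window_maximal_when_phase_centers_it(self):
        """The windowed mean of a pure fundamental peaks when its phase
        centres the 9-18 s window — the two response measures agree."""
        n_p, p_tr = 6, 14
        t = np.arange(n_p * p_tr)
        means = {}
        for phase_deg in range(0, 360, 8):
            ref = _boxcar_phase_rad(n_p, p_tr)
            series = np.cos(2 * np.pi * n_p * t / len(t) + ref
                            - np.deg2rad(phase_deg))
            pa = period_average(series.reshape(n_p, p_tr))
            means[phase_deg] = mean_response(pa)
        best = max(means, key=means.get)
        # the boxcar's own fundamental peaks at the C1 block centre (9 s);
        # the TR 3..6 window centres at 10.5 s, i.e. 1.5 s of extra delay
        window_center_deg = 360.0 * 1.5 / 42.0
        assert abs(wrap_deg(best - window_center_deg)) <= 10

    def test_single_period_rejected(self):
        with pytest.raises(ValueError, match="periods"):
            spectral_summary(np.zeros(14), 1, 14)


class TestCircularStats:
    @pytest.mark.parametrize("phases, expected", [
        ([10.0, 50.0], 30.0),
        ([120.0], 120.0),
        ([350.0, 10.0], 0.0),
    ])
    def test_circular_mean_handles_wraparound(self, phases, expected):
        mean, sd = circular_mean_sd(phases)
        assert wrap_deg(mean - expected) == pytest.approx(0.0, abs=1e-9)
        if len(phases) == 1:
            assert sd == 0.0

    def test_weighted_mean_tracks_heavy_vector(self):
        mean, _ = circular_mean_sd([0.0, 90.0], weights=[3.0, 1.0])
        assert 0.0 < mean < 45.0

    def test_zero_resultant_flagged(self):
        with pytest.raises(ValueError, match="resultant"):
            circular_mean_sd([0.0, 180.0])

    def test_sd_is_rms_of_wrapped_deviations(self):
        phases = [40.0, 80.0]
        _, sd = circular_mean_sd(phases)
        assert sd == pytest.approx(20.0, abs=1e-9)


class TestCompareGroups:
    def test_identical_groups_not_different(self):
        a = np.array([0.4, 0.5, 0.6, 0.45])
        _, p = compare_groups(a, a.copy(), "amplitude")
        assert p > 0.99

    def test_amplitude_power_matches_analytic(self):
        """Rejection rate for a 0.3% difference at within-group SD 0.15%,
        n = 8 vs 12, matches the two-sample t power."""
        na, nb, delta, sd = 8, 12, 0.3, 0.15
        df = na + nb - 2
        ncp = delta / (sd * np.sqrt(1 / na + 1 / nb))
        crit = stats.t.isf(0.025, df)
        power = stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
        rng = np.random.default_rng(11)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(0.7, sd, na)
            b = rng.normal(0.7 - delta, sd, nb)
            _, p = compare_groups(a, b, "amplitude")
            rej += p < 0.05
        sem = np.sqrt(power * (1 - power) / n_rep)
        assert rej / n_rep == pytest.approx(power, abs=3 * sem + 0.01)

    def test_phase_comparison_wraps_correctly(self):
        """Groups straddling 0 degrees are compared on the circle, not on
        raw numbers."""
        rng = np.random.default_rng(5)
        a = (rng.normal(350.0, 5.0, 10)) % 360.0
        b = (rng.normal(10.0, 5.0, 10)) % 360.0
        t, p = compare_groups(a, b, "phase")
        assert p < 0.01
        assert abs(t) < 50  # linearised difference ~20 deg, not ~340

    def test_phase_groups_with_reported_dispersions(self):
        """Von-Mises groups at the infant dispersions: the two-sided test
        rejects well above the alpha level for a 28-degree separation."""
        rng = np.random.default_rng(6)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            a = np.rad2deg(rng.vonmises(np.deg2rad(46), 1 / np.deg2rad(37) ** 2,
                                        8)) % 360
            b = np.rad2deg(rng.vonmises(np.deg2rad(74), 1 / np.deg2rad(32) ** 2,
                                        12)) % 360
            _, p = compare_groups(a, b, "phase")
            rej += p < 0.05
        assert 0.05 < rej / n_rep <= 1.0

    def test_degenerate_variance_shortcut(self):
        assert compare_groups([1.0, 1.0], [1.0, 1.0], "amplitude")[1] == 1.0
        assert compare_groups([1.0, 1.0], [2.0, 2.0], "amplitude")[1] == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0], "amplitude")
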