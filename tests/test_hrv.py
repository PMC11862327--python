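"""Time/frequency HRV indices and the sliding-window spectral protocol."""

import numpy as np
import pytest

from hrvcross.hrv import (
    HF_BAND,
    LF_BAND,
    build_window_grid,
    grade_windows,
    interpolate_rr_uniform,
    phase_hrv_summary,
    rmssd,
    sdrr,
    welch_band_power,
)
from hrvcross.rpeaks import RRSeries, reject_rr_artifacts
from hrvcross.simulate import RrSimConfig, analytic_indices, generate_rr_series


def clean_from(values, valid=None):
    vals = np.asarray(values, dtype=float)
    rr = RRSeries(onsets=np.cumsum(np.r_[0.0, vals[:-1]]) / 1000.0, intervals=vals)
    clean = reject_rr_artifacts(rr)
    if valid is not None:
        clean.valid_mask = np.asarray(valid, dtype=bool)
    return clean


class TestTimeDomain:
    @pytest.mark.parametrize(
        "values,expected",
        [([800.0, 800, 800], 0.0), ([800.0, 900, 1000], 100.0),
         ([800.0, 900], np.sqrt(5000.0))],
    )
    def test_sdrr_hand_values(self, values, expected):
        assert sdrr(clean_from(values)) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "values,expected",
        [([850.0] * 5, 0.0), ([800.0, 810, 790], np.sqrt(250.0))],
    )
    def test_rmssd_hand_values(self, values, expected):
        assert rmssd(clean_from(values)) == pytest.approx(expected, abs=1e-9)

    def test_rmssd_skips_gaps(self):
        # deleted second interval: only the (900, 910) pair contributes
        clean = clean_from([800.0, 850, 900, 910], valid=[True, False, True, True])
        assert rmssd(clean) == pytest.approx(10.0)

    def test_errors_on_degenerate_input(self):
        with pytest.raises(ValueError):
            sdrr(clean_from([800.0, 900], valid=[True, False]))
        with pytest.raises(ValueError):
            rmssd(clean_from([800.0, 900, 1000], valid=[True, False, True]))

    def test_rmssd_bounded_by_sdrr(self):
        # stationary series: RMSSD <= sqrt(2)*SDRR
        for seed in range(5):
            rr = generate_rr_series(RrSimConfig(duration=600.0, seed=seed))
            clean = reject_rr_artifacts(rr)
            assert rmssd(clean) <= np.sqrt(2.0) * sdrr(clean) * 1.001


class TestWindowGrid:
    def test_window_counts(self):
        assert len(build_window_grid(1800.0)) == 49
        assert len(build_window_grid(360.0)) == 1
        with pytest.raises(ValueError):
            build_window_grid(359.0)

    def test_grid_geometry(self):
        grid = build_window_grid(600.0)
        starts = [w.start for w in grid.windows]
        assert starts == pytest.approx(np.arange(0.0, 241.0, 30.0))
        assert all(w.end - w.start == 360.0 for w in grid.windows)

    def test_rejection_rule_20_percent(self, steady_rr):
        clean = reject_rr_artifacts(steady_rr)
        # carve out 90 s (25%) of a 360 s window
        mask = (clean.onsets > 100.0) & (clean.onsets < 190.0)
        clean.valid_mask[mask] = False
        grid = grade_windows(clean, build_window_grid(300.0, window_length=290.0))
        first = grid.windows[0]
        assert first.usable_fraction < 0.80
        assert not first.accepted


class TestInterpolationAndWelch:
    def test_constant_series_constant_tachogram(self, steady_rr):
        clean = reject_rr_artifacts(
            generate_rr_series(RrSimConfig(duration=400.0, mean_rr=1000.0, lf_amp=0,
                                           hf_amp=0, broadband_sd=0, seed=0))
        )
        grid = grade_windows(clean, build_window_grid(400.0))
        _, tach = interpolate_rr_uniform(clean, grid.windows[0])
        assert np.allclose(tach, 1000.0, atol=1e-6)

    def test_sinusoid_dominant_frequency_preserved(self):
        cfg = RrSimConfig(duration=400.0, mean_rr=1000.0, lf_amp=0, hf_amp=25,
                          broadband_sd=0, resp_freq=0.25, seed=1)
        clean = reject_rr_artifacts(generate_rr_series(cfg))
        grid = grade_windows(clean, build_window_grid(400.0))
        t, tach = interpolate_rr_uniform(clean, grid.windows[0])
        spec = np.abs(np.fft.rfft(tach - tach.mean()))
        freqs = np.fft.rfftfreq(tach.size, d=t[1] - t[0])
        assert freqs[np.argmax(spec)] == pytest.approx(0.25, abs=0.01)

    def test_rejected_window_not_interpolated(self, steady_rr):
        clean = reject_rr_artifacts(steady_rr)
        grid = grade_windows(clean, build_window_grid(300.0, window_length=290.0))
        grid.windows[0].accepted = False
        with pytest.raises(ValueError, match="rejected"):
            interpolate_rr_uniform(clean, grid.windows[0])

    def test_pure_sinusoid_band_power(self):
        rate = 4.0
        t = np.arange(0, 360.0, 1 / rate)
        tach = 20.0 * np.sin(2 * np.pi * 0.25 * t)
        assert welch_band_power(tach, HF_BAND) == pytest.approx(200.0, rel=0.10)
        assert welch_band_power(tach, LF_BAND) < 2.0

    def test_parseval_total_power(self):
        rng = np.random.default_rng(3)
        tach = rng.normal(0, 12.0, int(360 * 4))
        total = welch_band_power(tach, (0.0, 2.0))
        assert total == pytest.approx(np.var(tach), rel=0.10)

    def test_zero_signal_zero_power(self):
        assert welch_band_power(np.zeros(1440), HF_BAND) == 0.0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            welch_band_power(np.zeros(1440), (0.5, 3.0))


class TestPhaseSummary:
    def test_summary_matches_generative_truth(self):
        cfg = RrSimConfig(duration=1200.0, seed=21)
        clean = reject_rr_artifacts(generate_rr_series(cfg))
        truth = analytic_indices(cfg)
        summ = phase_hrv_summary(clean)
        assert summ.hr == pytest.approx(truth["hr"], rel=0.02)
        assert summ.sdrr == pytest.approx(truth["sdrr"], rel=0.10)
        assert summ.rmssd == pytest.approx(truth["rmssd"], rel=0.10)
        assert summ.hf == pytest.approx(truth["hf"], rel=0.20)
        assert summ.resp_cpm == pytest.approx(truth["resp_cpm"], abs=1.0)
        assert summ.n_windows_used == 29

    def test_hf_invariant_to_window_offset(self):
        # stationary input: starting the grid 15 s later moves HF < 10%
        cfg = RrSimConfig(duration=800.0, seed=22)
        clean = reject_rr_artifacts(generate_rr_series(cfg))
        from hrvcross.hrv import interpolate_rr_uniform as interp, welch_band_power as wbp

        def hf_at_offset(t0):
            grid = grade_windows(clean, build_window_grid(770.0, t0=t0))
            vals = [wbp(interp(clean, w)[1], HF_BAND) for w in grid.accepted_windows]
            return np.mean(vals)

        a, b = hf_at_offset(0.0), hf_at_offset(15.0)
        assert abs(a - b) / a < 0.10

    def test_doubling_hf_amp_quadruples_hf(self):
        def hf_for(amp, seed):
            cfg = RrSimConfig(duration=1200.0, mean_rr=900.0, lf_amp=10.0,
                              hf_amp=amp, broadband_sd=5.0, seed=seed)
            return phase_hrv_summary(reject_rr_artifacts(generate_rr_series(cfg))).hf

        h1 = np.mean([hf_for(20.0, s) for s in range(3)])
        h2 = np.mean([hf_for(40.0, s) for s in range(3)])
        # subtract the small broadband floor contribution before comparing
        floor = 2 * 5.0**2 * 0.9 * 0.25
        assert (h2 - floor) / (h1 - floor) == pytest.approx(4.0, rel=0.15)

    def test_single_accepted_window_equals_window_value(self):
        cfg = RrSimConfig(duration=365.0, seed=23)
        clean = reject_rr_artifacts(generate_rr_series(cfg))
        summ = phase_hrv_summary(clean, phase_duration=365.0)
        assert summ.n_windows_used == 1
        grid = grade_windows(clean, build_window_grid(365.0, t0=float(clean.onsets[0])))
        _, tach = interpolate_rr_uniform(clean, grid.windows[0])
        assert summ.hf == pytest.approx(welch_band_power(tach, HF_BAND))

    def test_lfhf_aggregation_variants(self):
        cfg = RrSimConfig(duration=800.0, seed=25)
        clean = reject_rr_artifacts(generate_rr_series(cfg))
        per_window = phase_hrv_summary(clean)
        ratio_of_means = phase_hrv_summary(clean, lfhf_ratio_of_means=True)
        assert ratio_of_means.lfhf == pytest.approx(
            ratio_of_means.lf / ratio_of_means.hf)
        # both aggregations estimate the same stationary quantity
        assert per_window.lfhf == pytest.approx(ratio_of_means.lfhf, rel=0.2)

    def test_short_phase_reports_time_domain_only(self):
        cfg = RrSimConfig(duration=120.0, seed=24)
        clean = reject_rr_artifacts(generate_rr_series(cfg))
        summ = phase_hrv_summary(clean, phase_duration=120.0)
        assert summ.hf is None and summ.lf is None and summ.lfhf is None
        assert summ.sdrr > 0 and summ.rmssd > 0
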