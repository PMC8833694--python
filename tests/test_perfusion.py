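"""Bolus-kinetics estimation: gate, arrival, fit, TTP, WiR, equivariances."""

import numpy as np
import pytest

from lnscore import (
    BolusFit,
    TimeIntensityCurve,
    analyze_tic,
    compute_ttp,
    compute_wir,
    estimate_baseline_and_arrival,
    fit_bolus,
    generate_tic,
    lognormal_bolus,
    quality_gate,
)
from lnscore.errors import InsufficientDataError, InvalidInputError, NoEnhancementError


def make_tic(intensity, rate=20.0, excluded=None):
    n = len(intensity)
    return TimeIntensityCurve(
        time_s=np.arange(n) / rate,
        intensity=np.asarray(intensity, dtype=float),
        excluded=np.zeros(n, bool) if excluded is None else excluded,
    )


class TestQualityGate:
    @pytest.mark.parametrize(
        "frac,ok", [(0.0, True), (0.6, False), (0.4, True)]  # gate is inclusive
    )
    def test_gate_thresholds(self, frac, ok):
        n = 100
        excluded = np.zeros(n, bool)
        excluded[: int(frac * n)] = True
        tic = make_tic(np.ones(n), excluded=excluded)
        assert quality_gate(tic, 0.4) is ok

    def test_unusable_curve_yields_unavailable_params(self):
        tic = generate_tic(5.0, 1.0, 0.5, 30.0, 1.0, 20.0, 1000, 0.1, 0.6, seed=3)
        params = analyze_tic(tic)
        assert not params.usable
        assert params.excluded_fraction == pytest.approx(0.6)
        assert np.isnan(params.ttp_s)


class TestArrivalDetection:
    def test_noiseless_arrival_within_one_frame(self):
        tic = generate_tic(5.0, 0.5, 0.5, 20.0, 1.0, 20.0, 1000, 0.0, 0.0, seed=1)
        baseline, t_arr = estimate_baseline_and_arrival(tic)
        assert baseline == pytest.approx(1.0)
        assert abs(t_arr - 5.0) <= 1.0 / 20.0 + 1e-9

    def test_flat_curve_raises_no_enhancement(self):
        tic = generate_tic(5.0, 0.5, 0.5, 0.0, 2.0, 20.0, 200, 0.0, 0.0, seed=1)
        with pytest.raises(NoEnhancementError):
            estimate_baseline_and_arrival(tic)

    def test_arrival_bias_small_over_100_seeds(self):
        # fitted arrival vs generator truth, 10% peak noise
        biases = []
        for i in range(100):
            mu, sigma, amp = 1.0, 0.5, 40.0
            peak = lognormal_bolus(
                np.linspace(0.01, 30, 2000), 0, mu, sigma, amp, 0
            ).max()
            tic = generate_tic(
                6.0, mu, sigma, amp, 1.0, 20.0, 1000, 0.1 * peak, 0.0, seed=500 + i
            )
            params = analyze_tic(tic)
            biases.append(params.t_arrival_s - 6.0)
        assert abs(np.mean(biases)) < 0.25


class TestBolusFit:
    def test_noiseless_parameter_recovery_within_one_percent(self):
        mu, sigma, amp = 1.2, 0.45, 35.0
        tic = generate_tic(5.0, mu, sigma, amp, 2.0, 20.0, 1000, 0.0, 0.0, seed=1)
        baseline, t_arr = estimate_baseline_and_arrival(tic)
        fit = fit_bolus(tic, baseline, t_arr)
        assert fit.mu == pytest.approx(mu, rel=0.01)
        assert fit.sigma == pytest.approx(sigma, rel=0.01)
        assert fit.amplitude == pytest.approx(amp, rel=0.01)
        assert fit.t_arrival_s == pytest.approx(5.0, abs=0.05)
        # fitted peak sits at arrival + lognormal mode
        t_peak = fit.t_arrival_s + compute_ttp(fit)
        dense = np.linspace(4.0, 30.0, 200_000)
        assert t_peak == pytest.approx(dense[np.argmax(fit.predict(dense))], abs=1e-3)

    def test_ttp_closed_form(self):
        fit = BolusFit(0.0, 0.0, 0.5, 1.0, 0.0, 0.0, True)
        assert compute_ttp(fit) == pytest.approx(np.exp(-0.25))
        # sigma -> 0 limit: mode -> exp(mu)
        fit_sharp = BolusFit(0.0, 1.0, 1e-4, 1.0, 0.0, 0.0, True)
        assert compute_ttp(fit_sharp) == pytest.approx(np.exp(1.0), rel=1e-4)

    def test_fitted_ttp_matches_dense_argmax_of_generated_curve(self):
        # mu 0, sigma 0.5 -> mode at exp(-0.25) = 0.7788 s after arrival
        tic = generate_tic(5.0, 0.0, 0.5, 10.0, 1.0, 20.0, 1000, 0.0, 0.0, seed=1)
        params = analyze_tic(tic)
        assert params.ttp_s == pytest.approx(np.exp(-0.25), rel=0.05)
        dense = np.linspace(5.001, 15.0, 400_000)
        argmax = dense[
            np.argmax(lognormal_bolus(dense, 5.0, 0.0, 0.5, 10.0, 1.0))
        ]
        assert params.ttp_s == pytest.approx(argmax - 5.0, rel=0.01)

    def test_sampled_argmax_at_lognormal_mode(self):
        tic = generate_tic(5.0, 0.8, 0.5, 25.0, 1.0, 20.0, 1000, 0.0, 0.0, seed=2)
        t_argmax = tic.time_s[np.argmax(tic.intensity)]
        assert t_argmax == pytest.approx(5.0 + np.exp(0.8 - 0.25), abs=1.0 / 20.0)


class TestWir:
    def test_linear_ramp_slope(self):
        t = np.arange(200) / 20.0
        fit = BolusFit(0.0, 0.0, 0.5, 1.0, 0.0, 0.0, True)
        tic = make_tic(2.0 * t)
        assert compute_wir(tic, fit, 0.0, 5.0, source="raw") == pytest.approx(2.0)

    def test_monotone_washin_has_positive_slope(self):
        tic = generate_tic(2.0, 1.0, 0.5, 30.0, 1.0, 20.0, 500, 0.0, 0.0, seed=1)
        params = analyze_tic(tic)
        assert params.wir_au_per_s > 0

    def test_raw_and_fitted_modes_agree_at_low_noise(self):
        diffs = []
        for i in range(30):
            mu, sigma, amp = 1.1, 0.5, 40.0
            peak = lognormal_bolus(
                np.linspace(0.01, 30, 2000), 0, mu, sigma, amp, 0
            ).max()
            tic = generate_tic(
                6.0, mu, sigma, amp, 1.0, 20.0, 1000, 0.05 * peak, 0.0, seed=700 + i
            )
            pf = analyze_tic(tic, wir_source="fitted")
            pr = analyze_tic(tic, wir_source="raw")
            diffs.append(abs(pf.wir_au_per_s - pr.wir_au_per_s) / pf.wir_au_per_s)
        assert np.median(diffs) < 0.10

    def test_window_validation(self):
        fit = BolusFit(0.0, 0.0, 0.5, 1.0, 0.0, 0.0, True)
        tic = make_tic(np.ones(100))
        with pytest.raises(InvalidInputError):
            compute_wir(tic, fit, 5.0, 5.0)
        with pytest.raises(InsufficientDataError):
            compute_wir(tic, fit, 0.0, 0.05, source="raw")


class TestEquivariance:
    def test_time_shift_moves_arrival_not_ttp_or_wir(self):
        tic = generate_tic(6.0, 1.0, 0.5, 40.0, 1.0, 20.0, 1000, 0.3, 0.0, seed=11)
        shifted = TimeIntensityCurve(
            tic.time_s + 3.7, tic.intensity, tic.excluded
        )
        a = analyze_tic(tic)
        b = analyze_tic(shifted)
        assert b.t_arrival_s - a.t_arrival_s == pytest.approx(3.7, abs=1e-3)
        assert b.t_peak_s - a.t_peak_s == pytest.approx(3.7, abs=1e-2)
        assert b.ttp_s == pytest.approx(a.ttp_s, rel=1e-3)
        assert b.wir_au_per_s == pytest.approx(a.wir_au_per_s, rel=1e-3)

    def test_intensity_scaling_scales_wir_not_ttp(self):
        tic = generate_tic(6.0, 1.0, 0.5, 40.0, 1.0, 20.0, 1000, 0.3, 0.0, seed=12)
        scaled = TimeIntensityCurve(tic.time_s, 2.5 * tic.intensity, tic.excluded)
        a = analyze_tic(tic)
        b = analyze_tic(scaled)
        assert b.ttp_s == pytest.approx(a.ttp_s, rel=1e-3)
        assert b.wir_au_per_s == pytest.approx(2.5 * a.wir_au_per_s, rel=1e-3)
        assert b.peak_enhancement_au == pytest.approx(
            2.5 * a.peak_enhancement_au, rel=1e-3
        )

    def test_excluded_frames_never_influence_results(self):
        tic = generate_tic(6.0, 1.0, 0.5, 40.0, 1.0, 20.0, 1000, 0.2, 0.15, seed=13)
        corrupted = tic.intensity.copy()
        corrupted[tic.excluded] = 1e6  # garbage on masked frames only
        a = analyze_tic(tic)
        b = analyze_tic(TimeIntensityCurve(tic.time_s, corrupted, tic.excluded))
        assert b.ttp_s == a.ttp_s
        assert b.wir_au_per_s == a.wir_au_per_s
        assert b.fit_rmse == a.fit_rmse


class TestValidation:
    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            make_tic(np.ones(10))

    def test_nonincreasing_times_rejected(self):
        t = np.arange(100.0)
        t[50] = t[49]
        with pytest.raises(InvalidInputError):
            TimeIntensityCurve(t, np.ones(100), np.zeros(100, bool))
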