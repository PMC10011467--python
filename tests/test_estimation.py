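"""Parameter identification: recovery oracles, error metric, cohort summaries."""

import numpy as np
import pytest

from windkessel3 import (FitSettings, PatientRecord, WK3Params, Waveform,
                         fit_cohort, fit_wk3, l2_relative_error,
                         normalize_params, simulate_pressure, waveform_mean)
from windkessel3.synthetic import DEFAULT_TEMPLATES, make_flow_template


def synthetic_pair(artery, params, qbar, period, noise_sd=0.0, seed=0):
    """Flow from the artery template, pressure from the exact forward model."""
    flow = make_flow_template(DEFAULT_TEMPLATES[artery]).to_waveform(qbar, period)
    pressure = simulate_pressure(flow, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pressure = Waveform(time=pressure.time,
                            value=pressure.value + rng.normal(0, noise_sd, pressure.value.size),
                            period=period, quantity="pressure")
    return flow, pressure


class TestL2RelativeError:
    def test_identical_is_zero(self, carotid_flow):
        assert l2_relative_error(carotid_flow.value, carotid_flow.value) == 0.0

    def test_doubling_is_hundred_percent(self):
        v = np.array([90.0, 100.0, 85.0])
        assert l2_relative_error(2 * v, v) == pytest.approx(100.0)

    def test_two_point_example(self):
        # sqrt((10^2 + 10^2) / (100^2 + 100^2)) * 100 = 10
        assert l2_relative_error([110.0, 90.0], [100.0, 100.0]) == pytest.approx(10.0)

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="grid"):
            l2_relative_error(np.ones(3), np.ones(4))

    def test_zero_norm_expected_errors(self):
        with pytest.raises(ValueError, match="zero norm"):
            l2_relative_error(np.ones(3), np.zeros(3))


class TestFitRecovery:
    @pytest.mark.parametrize("artery,params", [
        ("cca", WK3Params(1.14, 10.35, 0.04)),
        ("sa", WK3Params(0.96, 33.10, 0.06)),
    ])
    def test_noiseless_recovery_within_half_percent(self, artery, params):
        qbar = {"cca": 7.63, "sa": 3.08}[artery]
        flow, pressure = synthetic_pair(artery, params, qbar, 0.952)
        fr = fit_wk3(flow, pressure, artery=artery)
        truth = normalize_params(params, 0.952)
        assert fr.converged
        assert fr.normalized.r1norm == pytest.approx(truth.r1norm, rel=5e-3)
        assert fr.normalized.cnorm == pytest.approx(truth.cnorm, rel=5e-3)
        assert fr.sse < 1e-6

    def test_rtot_constraint_exact(self, carotid_flow, carotid_params):
        pressure = simulate_pressure(carotid_flow, carotid_params)
        fr = fit_wk3(carotid_flow, pressure)
        rtot = waveform_mean(pressure) / waveform_mean(carotid_flow)
        assert fr.params.r1 + fr.params.r2 == pytest.approx(rtot, abs=1e-9)

    def test_cost_history_non_increasing(self, carotid_flow):
        params = WK3Params(2.0, 9.0, 0.08)
        pressure = simulate_pressure(carotid_flow, params)
        fr = fit_wk3(carotid_flow, pressure, settings=FitSettings(initial_guess=(0.4, 2.0)))
        assert np.all(np.diff(fr.cost_history) <= 0)

    def test_constant_flow_flagged_not_crashed(self):
        t = np.arange(100) / 100
        flow = Waveform(time=t, value=np.full(100, 5.0), period=1.0, quantity="flow")
        pressure = Waveform(time=t, value=np.full(100, 55.0), period=1.0,
                            quantity="pressure")
        fr = fit_wk3(flow, pressure, settings=FitSettings(initial_guess=(0.2, 0.7)))
        assert not fr.identifiable
        assert fr.converged
        assert fr.normalized.r1norm == pytest.approx(0.2)
        assert fr.sse == pytest.approx(0.0, abs=1e-12)

    def test_noise_robustness_median_within_five_percent(self):
        params = WK3Params(1.14, 10.35, 0.04)
        truth = normalize_params(params, 0.952)
        r1s, cns = [], []
        for seed in range(20):
            flow, pressure = synthetic_pair("cca", params, 7.63, 0.952,
                                            noise_sd=1.0, seed=seed)
            fr = fit_wk3(flow, pressure, artery="cca")
            r1s.append(fr.normalized.r1norm)
            cns.append(fr.normalized.cnorm)
        assert np.median(r1s) == pytest.approx(truth.r1norm, rel=0.05)
        assert np.median(cns) == pytest.approx(truth.cnorm, rel=0.05)

    def test_scale_invariance_of_normalized_parameters(self, carotid_flow):
        # scaling pressure by alpha scales R1, R2 by alpha and C by 1/alpha
        params = WK3Params(1.5, 12.0, 0.05)
        pressure = simulate_pressure(carotid_flow, params)
        alpha = 1.3
        scaled = Waveform(time=pressure.time, value=alpha * pressure.value,
                          period=pressure.period, quantity="pressure")
        fa = fit_wk3(carotid_flow, pressure)
        fb = fit_wk3(carotid_flow, scaled)
        assert fb.params.r1 == pytest.approx(alpha * fa.params.r1, rel=1e-3)
        assert fb.params.c == pytest.approx(fa.params.c / alpha, rel=1e-3)
        assert fb.normalized.r1norm == pytest.approx(fa.normalized.r1norm, rel=1e-3)
        assert fb.normalized.cnorm == pytest.approx(fa.normalized.cnorm, rel=1e-3)

    def test_period_invariance_of_normalized_parameters(self):
        params = WK3Params(1.14, 10.35, 0.04)
        fits = []
        for beta in (1.0, 1.4):
            T = 0.952 * beta
            flow = make_flow_template(DEFAULT_TEMPLATES["cca"]).to_waveform(7.63, T)
            scaled_params = WK3Params(params.r1, params.r2, params.c * beta)
            pressure = simulate_pressure(flow, scaled_params)
            fits.append(fit_wk3(flow, pressure))
        assert fits[1].normalized.r1norm == pytest.approx(fits[0].normalized.r1norm, rel=1e-3)
        assert fits[1].normalized.cnorm == pytest.approx(fits[0].normalized.cnorm, rel=1e-3)


class TestCohort:
    def test_degenerate_cohort_median_equals_single_fit(self, carotid_flow, carotid_params):
        pressure = simulate_pressure(carotid_flow, carotid_params)
        recs = [PatientRecord(f"p{i}", "cca", carotid_flow, pressure) for i in range(3)]
        cohort = fit_cohort(recs)
        single = fit_wk3(carotid_flow, pressure, artery="cca")
        row = cohort.summary.loc["cca"]
        assert row["r1norm_median"] == pytest.approx(single.normalized.r1norm, rel=1e-6)
        assert row["r1norm_q75"] - row["r1norm_q25"] == pytest.approx(0.0, abs=1e-9)

    def test_quantile_rule_matches_linear_interpolation(self, carotid_flow):
        # three fits with r1norm 0.1/0.2/0.3 -> median 0.2, IQR (0.15, 0.25)
        recs = []
        for i, r1n in enumerate((0.1, 0.2, 0.3)):
            rtot = 11.49
            params = WK3Params(r1n * rtot, (1 - r1n) * rtot, 0.04)
            pressure = simulate_pressure(carotid_flow, params)
            recs.append(PatientRecord(f"p{i}", "cca", carotid_flow, pressure))
        cohort = fit_cohort(recs)
        row = cohort.summary.loc["cca"]
        assert row["r1norm_median"] == pytest.approx(0.2, abs=2e-3)
        assert row["r1norm_q25"] == pytest.approx(0.15, abs=2e-3)
        assert row["r1norm_q75"] == pytest.approx(0.25, abs=2e-3)

    def test_failures_flagged_not_fatal(self, carotid_flow, carotid_params):
        pressure = simulate_pressure(carotid_flow, carotid_params)
        bad_flow = Waveform(time=carotid_flow.time,
                            value=carotid_flow.value - waveform_mean(carotid_flow),
                            period=carotid_flow.period, quantity="flow")
        recs = [PatientRecord("good", "cca", carotid_flow, pressure),
                PatientRecord("bad", "cca", bad_flow, pressure)]
        cohort = fit_cohort(recs)
        assert isinstance(cohort.fits[("bad", "cca")], str)
        assert cohort.summary.loc["cca", "n"] == 1
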