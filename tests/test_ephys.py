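"""Current-trace fitting, kinetic classification, binning, ΔF/F0, chi-squared."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coromorph import ephys


def exp_trace(tau_ms, amp=-100.0, onset_ms=5.0, dt=0.1, length_ms=None,
              noise_sd=0.0, seed=0):
    length_ms = length_ms or max(20.0, 8 * tau_ms)
    t = np.arange(0, length_ms, dt)
    I = np.zeros_like(t)
    post = t >= onset_ms
    I[post] = amp * np.exp(-(t[post] - onset_ms) / tau_ms)
    if noise_sd:
        I = I + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return ephys.CurrentTrace(I, dt_ms=dt, stimulus_onset_ms=onset_ms)


class TestFitInactivationTau:
    def test_noise_free_exact_recovery(self):
        fit = ephys.fit_inactivation_tau(exp_trace(3.0))
        assert fit.converged
        assert fit.tau_ms == pytest.approx(3.0, rel=1e-3)

    def test_flat_trace_reports_no_current(self):
        t = np.random.default_rng(0).normal(0, 1.0, 500)
        fit = ephys.fit_inactivation_tau(
            ephys.CurrentTrace(t, dt_ms=0.1, stimulus_onset_ms=5.0))
        assert fit.no_current
        assert fit.tau_ms is None

    def test_noisy_median_recovery(self):
        # 5% noise: the fitted constants must center on the truth
        taus = []
        for seed in range(100):
            fit = ephys.fit_inactivation_tau(
                exp_trace(20.0, noise_sd=5.0, seed=seed))
            if fit.tau_ms is not None:
                taus.append(fit.tau_ms)
        assert len(taus) >= 95
        assert np.median(taus) == pytest.approx(20.0, rel=0.05)

    def test_latency_filter_rejects_slow_onset(self):
        tr = exp_trace(5.0, onset_ms=5.0)
        # shift the response 8 ms after the nominal onset
        shifted = np.concatenate([tr.current_pA[:50],
                                  np.zeros(80), tr.current_pA[50:-80]])
        tr2 = ephys.CurrentTrace(shifted, dt_ms=0.1, stimulus_onset_ms=5.0)
        fit = ephys.fit_inactivation_tau(tr2, max_latency_ms=5.0)
        assert fit.no_current

    def test_positive_going_current(self):
        fit = ephys.fit_inactivation_tau(exp_trace(10.0, amp=80.0))
        assert fit.tau_ms == pytest.approx(10.0, rel=1e-3)


class TestClassifyCurrent:
    @pytest.mark.parametrize("tau,cls", [
        (3.0, "RA"), (4.999, "RA"),
        (5.0, "IA"), (30.0, "IA"), (50.0, "IA"),
        (50.001, "SA"), (51.0, "SA"), (1000.0, "SA"),
    ])
    def test_bins(self, tau, cls):
        assert ephys.classify_current(tau) == cls

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ephys.classify_current(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    def test_partition(self, tau):
        assert ephys.classify_current(tau) in {"RA", "IA", "SA"}


class TestBinDeflectionResponses:
    def test_small_deflections_average_in_first_bin(self):
        out = ephys.bin_deflection_responses(
            ephys.DeflectionSeries([(5, -10.0), (8, -20.0)]))
        assert out[(1, 10)] == pytest.approx(-15.0)
        assert all(np.isnan(v) for k, v in out.items() if k != (1, 10))

    def test_over_limit_stimuli_discarded(self):
        out = ephys.bin_deflection_responses(
            ephys.DeflectionSeries([(1200, -50.0), (600, -30.0)]))
        assert out[(501, 1000)] == pytest.approx(-30.0)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            ephys.bin_deflection_responses(
                ephys.DeflectionSeries([(1500, -50.0)]))

    def test_binned_means_match_linear_response(self):
        # response proportional to deflection: bin means = mean of member stimuli
        stim = [1, 5, 10, 20, 40, 75, 150, 400, 800]
        series = ephys.DeflectionSeries([(d, -0.5 * d) for d in stim])
        out = ephys.bin_deflection_responses(series)
        for (lo, hi), val in out.items():
            members = [d for d in stim if lo <= d <= hi]
            if members:
                assert val == pytest.approx(-0.5 * np.mean(members))

    def test_nonpositive_deflection_rejected(self):
        with pytest.raises(ValueError):
            ephys.DeflectionSeries([(0.0, -1.0)])


class TestDff:
    def test_constant_trace_maps_to_zero(self):
        out = ephys.dff(ephys.FluorescenceTrace(np.full(30, 250.0)))
        np.testing.assert_allclose(out, 0.0)

    def test_step_amplitude(self):
        F = np.concatenate([np.full(10, 100.0), np.full(5, 150.0)])
        out = ephys.dff(ephys.FluorescenceTrace(F))
        assert out[-1] == pytest.approx(0.5)

    def test_baseline_mean_is_zero_by_construction(self, rng):
        for _ in range(10):
            F = rng.uniform(50, 500, size=40)
            out = ephys.dff(ephys.FluorescenceTrace(F))
            assert abs(out[:10].mean()) < 1e-12

    def test_noisy_plateau_recovery(self):
        plateaus = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            F = np.concatenate([np.full(10, 200.0), np.full(30, 300.0)])
            F = F * (1 + r.normal(0, 0.01, F.size))
            plateaus.append(ephys.dff(ephys.FluorescenceTrace(F))[10:].mean())
        assert np.mean(plateaus) == pytest.approx(0.5, rel=0.02)

    def test_ionomycin_normalization(self):
        F = np.concatenate([np.full(10, 100.0), np.full(5, 200.0)])
        raw, scaled = ephys.dff(ephys.FluorescenceTrace(F, ionomycin_max=500.0))
        assert raw[-1] == pytest.approx(1.0)
        assert scaled[-1] == pytest.approx(1.0 / 4.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            ephys.dff(ephys.FluorescenceTrace(np.zeros(20)))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ephys.dff(ephys.FluorescenceTrace(np.full(5, 1.0)))


class TestCompareClassProportions:
    def test_identical_distributions_give_zero_statistic(self):
        stat, p = ephys.compare_class_proportions([8, 4, 2], [8, 4, 2])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_table_statistic(self):
        # hand evaluation of the Pearson formula on [[10,0],[0,10]]
        stat, p = ephys.compare_class_proportions([10, 0], [0, 10])
        assert stat == pytest.approx(20.0)

    def test_group_swap_invariance(self):
        a, b = [12, 3, 1], [5, 9, 4]
        assert ephys.compare_class_proportions(a, b)[0] == \
            pytest.approx(ephys.compare_class_proportions(b, a)[0])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ephys.compare_class_proportions([0, 0], [0, 0])
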