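import numpy as np
import pytest

from pfcsim.analysis import (
    compare_samples,
    evoked_latency,
    evoked_spike_count,
    isi_autocorrelation,
    isi_statistics,
    ks_compare,
    lfp_psd,
    make_surrogate_invivo,
    pooled_autocorrelation_halfwidth,
    population_cc0,
    vm_fluctuation_sd,
    zero_lag_cc,
)


class TestISIStatistics:
    def test_periodic_train_has_zero_cv(self):
        st = isi_statistics(np.arange(0.0, 3000.0, 100.0))
        assert st.included and st.cv == pytest.approx(0.0)
        assert st.mean_isi == pytest.approx(100.0)

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(2)
        t = np.cumsum(rng.exponential(50.0, 10_000))
        st = isi_statistics(t)
        assert st.cv == pytest.approx(1.0, abs=0.02)

    def test_short_train_excluded_not_errored(self):
        st = isi_statistics(np.arange(9.0))
        assert not st.included and st.cv is None and st.mean_isi is None

    def test_global_time_shift_invariance(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.exponential(40.0, 200))
        a, b = isi_statistics(t), isi_statistics(t + 5000.0)
        assert a.cv == pytest.approx(b.cv, rel=1e-9)
        assert a.mean_isi == pytest.approx(b.mean_isi, rel=1e-9)


class TestAutocorrelation:
    def test_unit_zero_lag(self):
        rng = np.random.default_rng(4)
        ac = isi_autocorrelation(rng.exponential(1.0, 500), max_lag=10)
        assert ac[0] == pytest.approx(1.0)

    def test_iid_series_within_white_noise_band(self):
        rng = np.random.default_rng(5)
        x = rng.permutation(rng.exponential(1.0, 4000))
        ac = isi_autocorrelation(x, max_lag=20)
        assert np.all(np.abs(ac[1:]) < 2.5 / np.sqrt(len(x)))

    def test_local_mean_subtraction_removes_slow_drift(self):
        n = 2000
        drift = np.linspace(0.0, 5.0, n)
        rng = np.random.default_rng(6)
        x = drift + rng.normal(0, 0.3, n)
        raw = isi_autocorrelation(x, max_lag=5)
        corrected = isi_autocorrelation(x, max_lag=5, local_window=51)
        assert raw[1] > 0.9          # drift dominates
        assert abs(corrected[1]) < 0.2

    def test_pooled_halfwidth_on_known_process(self):
        # white ISI process: autocorrelation drops below 1/2 within one lag
        rng = np.random.default_rng(7)
        trains = [np.cumsum(rng.exponential(20.0, 300)) for _ in range(10)]
        hw = pooled_autocorrelation_halfwidth(trains, max_lag=10)
        assert hw is not None and hw <= 20.0


class TestZeroLagCC:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(8)
        t = np.cumsum(rng.exponential(30.0, 400))
        assert zero_lag_cc(t, t) == pytest.approx(1.0)

    def test_independent_poisson_trains_uncorrelated(self):
        rng = np.random.default_rng(9)
        cc = [zero_lag_cc(np.cumsum(rng.exponential(25.0, 2000)),
                          np.cumsum(rng.exponential(25.0, 2000)))
              for _ in range(20)]
        assert abs(np.mean(cc)) < 0.05

    def test_common_input_pair_exceeds_independent_control(self):
        rng = np.random.default_rng(10)
        # rate-comodulated pair: thinning of one mother train
        mother = np.cumsum(rng.exponential(5.0, 40_000))
        keep_a = rng.random(len(mother)) < 0.12
        keep_b = rng.random(len(mother)) < 0.12
        # slow gating makes the common drive visible at 200 ms resolution
        gate = (np.sin(2 * np.pi * mother / 4000.0) > 0)
        a, b = mother[keep_a & gate], mother[keep_b & gate]
        ind = np.cumsum(rng.exponential(np.diff(a).mean(), len(a)))
        cc_common = zero_lag_cc(a, b)
        cc_ind = zero_lag_cc(a, ind)
        assert cc_common > cc_ind
        assert cc_common > 0.1

    def test_counts_method(self):
        rng = np.random.default_rng(11)
        t = np.cumsum(rng.exponential(30.0, 500))
        assert zero_lag_cc(t, t, method="counts") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            zero_lag_cc(t, t, method="wavelet")

    def test_population_sampler_shape(self):
        rng = np.random.default_rng(12)
        trains = [np.cumsum(rng.exponential(40.0, 100)) for _ in range(8)]
        cc = population_cc0(trains, n_pairs=30, seed=0)
        assert len(cc) == 30 and np.all(np.abs(cc) <= 1.0)


class TestKSHarness:
    def test_identical_distribution_high_p(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 2000)
        d, p = ks_compare(x, x.copy(), seed=0)
        assert p > 0.4
        assert d < 0.3

    def test_gross_separation_rejected(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 500)
        b = rng.normal(5, 1, 500)
        _, p = ks_compare(a, b, seed=0)
        assert p < 1e-3

    def test_small_sample_threshold_near_asymptotic_formula(self):
        """The D at which p crosses 0.05 for n=m=30 sits within 15% of the
        asymptotic two-sample value c(0.05)*sqrt(2/30)."""
        from scipy.stats import ks_2samp

        n = 30
        target = 1.3581 * np.sqrt(2.0 / n)
        # exact p as a function of D via scipy's exact two-sample mode
        grid = np.linspace(0.2, 0.5, 61)
        crossing = None
        base = np.arange(n, dtype=float)
        for D in grid:
            k = int(round(D * n))
            shifted = base + k  # forces a max CDF gap of k/n
            p = ks_2samp(base, shifted, method="exact").pvalue
            if p <= 0.05:
                crossing = k / n
                break
        assert crossing is not None
        assert abs(crossing - target) / target < 0.15

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 300)
        b = rng.normal(0.3, 1.2, 300)
        d1, p1 = ks_compare(a, b, seed=3)
        d2, p2 = ks_compare(b, a, seed=3)
        assert d1 == pytest.approx(d2, abs=0.05)
        assert p1 == pytest.approx(p2, abs=0.1)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            ks_compare(np.arange(10), np.arange(100))

    def test_compare_samples_summary(self):
        rng = np.random.default_rng(16)
        a = {"cv": rng.normal(1, 0.3, 200), "isi": rng.normal(500, 100, 200)}
        b = {"cv": rng.normal(1, 0.3, 200), "isi": rng.normal(500, 100, 200)}
        rep = compare_samples(a, b, seed=0)
        assert set(rep.per_statistic) == {"cv", "isi"}
        assert rep.max_d >= max(v[0] for v in rep.per_statistic.values()) - 1e-12
        assert rep.min_p <= min(v[1] for v in rep.per_statistic.values()) + 1e-12


class TestLFP:
    def test_white_noise_flat_low_band(self):
        rng = np.random.default_rng(17)
        spec = lfp_psd(rng.normal(0, 1, 60_000), fs=1000.0)
        assert abs(spec.slope_low) < 0.2

    def test_integrated_noise_inverse_square(self):
        rng = np.random.default_rng(18)
        spec = lfp_psd(np.cumsum(rng.normal(0, 1, 60_000)), fs=1000.0)
        assert spec.slope_low == pytest.approx(-2.0, abs=0.2)

    def test_parseval_total_power(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0, 2.0, 60_000)
        spec = lfp_psd(x, fs=1000.0)
        power = np.trapezoid(spec.psd, spec.freq)
        assert power == pytest.approx(x.var(), rel=0.01)


class TestMembranePotential:
    def test_constant_trace(self):
        t = np.arange(1000.0)
        assert vm_fluctuation_sd(np.full(1000, -65.0), t, []) == 0.0

    def test_sinusoid_rms(self):
        t = np.arange(0.0, 10_000.0)
        v = 3.0 * np.sin(2 * np.pi * t / 250.0)
        assert vm_fluctuation_sd(v, t, []) == pytest.approx(3.0 / np.sqrt(2),
                                                            rel=1e-3)

    def test_spike_window_excision(self):
        t = np.arange(0.0, 1000.0)
        v = np.zeros(1000)
        v[500:505] = 40.0  # spike artifact
        sd_with = vm_fluctuation_sd(v, t, [])
        sd_without = vm_fluctuation_sd(v, t, [502.0])
        assert sd_without == 0.0 and sd_with > 1.0


class TestEvokedMeasures:
    def test_latency_of_synthetic_packet(self):
        rng = np.random.default_rng(20)
        baseline = rng.uniform(0, 500, 40)
        packet = rng.normal(212.0, 1.0, 120)
        lat = evoked_latency(np.concatenate([baseline, packet]), t0=200.0)
        assert lat == pytest.approx(12.0, abs=1.5)
        assert evoked_latency(np.array([]), 0.0) is None

    def test_evoked_count_baseline_subtraction(self):
        class R:
            spike_t = np.concatenate([np.linspace(0, 1000, 101),
                                      np.full(50, 1050.0)])
        n = evoked_spike_count(R, 1000.0, window=100.0, baseline=(0.0, 1000.0))
        assert n == pytest.approx(50 - 10, abs=3)


class TestSurrogate:
    def test_target_moments(self):
        s = make_surrogate_invivo(seed=1, n=10_000)
        assert s["cv"].mean() == pytest.approx(1.04, abs=3 * 0.33 / 100 + 0.02)
        assert (s["cv"] > 0).all()
        assert s["mean_isi"].mean() == pytest.approx(570.0, abs=3 * 610 / 100)
        assert s["mean_isi"].std() == pytest.approx(610.0, rel=0.1)
        assert s["cc0"].mean() == pytest.approx(2.4e-4, abs=1e-3)

    def test_seed_reproducibility(self):
        a = make_surrogate_invivo(seed=5)
        b = make_surrogate_invivo(seed=5)
        assert np.array_equal(a["cv"], b["cv"])

    def test_self_consistency_under_ks(self):
        a = make_surrogate_invivo(seed=1)
        b = make_surrogate_invivo(seed=2)
        rep = compare_samples(a, b, seed=0)
        assert rep.min_p > 0.05
        assert rep.max_d < 0.4
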