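"""OU input statistics, network integration, calibration, spikes."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from seqnet import netsim as ns
from seqnet import seqcore as sc
from seqnet.timeseries import TimeSeries, spikes_to_rate


class TestOUInput:
    def test_temporal_autocovariance(self):
        model = ns.InputModel(mu=0.0, Sigma_in=np.eye(2), tau_in=15.0)
        acs = []
        for seed in range(8):
            ts = ns.sample_ou_input(model, 60_000, 1.0, seed=seed)
            x = ts.values[0]
            for s in (5, 15, 30):
                acs.append((s, np.mean(x[s:] * x[:-s])))
        for s in (5, 15, 30):
            vals = [a for lag, a in acs if lag == s]
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - np.exp(-s / 15.0)) < 3 * se + 1e-3

    def test_stationary_mean(self):
        model = ns.InputModel(mu=0.1, Sigma_in=np.eye(3), tau_in=15.0)
        means = [ns.sample_ou_input(model, 50_000, 1.0, seed=s).values.mean()
                 for s in range(6)]
        se = np.std(means, ddof=1) / np.sqrt(6)
        assert abs(np.mean(means) - 0.1) < 3 * se + 1e-3

    def test_spatial_covariance(self):
        Sigma = np.array([[1.0, 0.9], [0.9, 1.0]])
        model = ns.InputModel(mu=0.0, Sigma_in=Sigma, tau_in=15.0)
        covs = []
        for seed in range(10):
            x = ns.sample_ou_input(model, 50_000, 1.0, seed=seed).values
            covs.append(np.cov(x))
        mean_cov = np.mean(covs, axis=0)
        se = np.std(covs, axis=0, ddof=1) / np.sqrt(10)
        assert np.all(np.abs(mean_cov - Sigma) < 3 * se + 1e-3)

    def test_non_psd_rejected_with_diagnostic(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            ns.sample_ou_input(ns.InputModel(Sigma_in=bad), 10, 1.0)

    def test_reproducible_given_seed(self):
        model = ns.InputModel(mu=0.1, Sigma_in=np.eye(2), tau_in=15.0)
        a = ns.sample_ou_input(model, 100, 1.0, seed=9)
        b = ns.sample_ou_input(model, 100, 1.0, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestSimulate:
    def test_zero_everything_stays_at_fixed_point(self):
        cfg = ns.NetworkConfig(T=100)
        zero_in = TimeSeries(np.zeros((3, 100)), 1.0)
        v, r = ns.simulate(np.zeros((3, 3)), zero_in, cfg)
        assert np.all(v.values == 0) and np.all(r.values == 0)

    def test_constant_input_relaxes_with_tau(self):
        cfg = ns.NetworkConfig(tau=20.0, dt=1.0, T=400)
        c = 0.7
        const = TimeSeries(np.full((1, 400), c), 1.0)
        v, _ = ns.simulate(np.zeros((1, 1)), const, cfg)
        t = np.arange(400)
        expected = c * (1 - (1 - cfg.dt / cfg.tau) ** t)  # discrete relaxation
        np.testing.assert_allclose(v.values[0], expected, atol=1e-10)
        assert abs(v.values[0, -1] - c) < 1e-4

    def test_one_unit_variance_matches_quadrature(self):
        """Linear 1-unit net, self-weight w: stationary var via spectral integral."""
        w, tau, tau_in, sig2 = 0.5, 20.0, 15.0, 1.0
        a = (1 - w) / tau

        def integrand(om):
            s_xi = 2 * sig2 * tau_in / (1 + (om * tau_in) ** 2)
            return s_xi / (tau**2 * (a**2 + om**2)) / (2 * np.pi)

        expected, _ = integrate.quad(integrand, -np.inf, np.inf)
        model = ns.InputModel(mu=0.0, Sigma_in=np.array([[sig2]]), tau_in=tau_in)
        cfg = ns.NetworkConfig(tau=tau, dt=1.0, T=100_000)
        vs = []
        for seed in range(10):
            v, _, _ = ns.run_network(np.array([[w]]), model, cfg, seed=seed)
            vs.append(v.values.var())
        se = np.std(vs, ddof=1) / np.sqrt(10)
        assert abs(np.mean(vs) - expected) < 3 * se + 0.01 * expected

    def test_blowup_aborts_with_step_index(self):
        cfg = ns.NetworkConfig(tau=20.0, dt=1.0, T=5000, blowup_bound=100.0)
        drive = TimeSeries(np.ones((1, 5000)), 1.0)
        with pytest.raises(ns.SimulationDiverged, match="rescaling"):
            ns.simulate(np.array([[3.0]]), drive, cfg)

    def test_bit_reproducible(self):
        model = ns.InputModel(mu=0.1, Sigma_in=np.eye(4), tau_in=15.0)
        cfg = ns.NetworkConfig(T=2000)
        W = np.full((4, 4), 0.1)
        a, _, _ = ns.run_network(W, model, cfg, seed=5)
        b, _, _ = ns.run_network(W, model, cfg, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestCalibration:
    def test_linear_is_noop(self):
        cfg = ns.NetworkConfig(nonlinearity="linear")
        assert ns.calibrate_relu_slope(np.eye(2) * 0.1, None, cfg) == 1.0

    def test_target_mean_rate_reached_on_fresh_seed(self):
        from seqnet import connectivity as cn

        S = cn.make_input_covariance("fixed_corr", N=20, seed=0)
        W = cn.random_ensemble("symmetric", 20, seed=1)
        model = ns.InputModel(mu=0.1, Sigma_in=S, tau_in=15.0)
        cfg = ns.NetworkConfig(nonlinearity="relu_clipped", T=30_000,
                               target_mean_rate=0.1)
        slope = ns.calibrate_relu_slope(W, model, cfg, seed=11, tol=0.01)
        cfg2 = dataclasses.replace(cfg, slope=slope)
        _, r, _ = ns.run_network(W, model, cfg2, seed=99)
        assert abs(r.values.mean() - 0.1) <= 0.01

    def test_mean_rate_monotone_in_slope(self):
        from seqnet import connectivity as cn

        S = cn.make_input_covariance("fixed_corr", N=10, seed=2)
        W = cn.random_ensemble("symmetric", 10, seed=3)
        model = ns.InputModel(mu=0.1, Sigma_in=S, tau_in=15.0)
        xi = ns.sample_ou_input(model, 10_000, 1.0, seed=4)
        means = []
        for slope in (0.05, 0.2, 0.8):
            cfg = ns.NetworkConfig(nonlinearity="relu_clipped", slope=slope,
                                   T=10_000)
            _, r = ns.simulate(W, xi, cfg)
            means.append(r.values.mean())
        assert means[0] < means[1] < means[2]


class TestPoissonSpikes:
    def test_zero_rates_no_spikes(self):
        rates = TimeSeries(np.zeros((2, 100)), 1.0)
        assert ns.poisson_spikes(rates, seed=0) == []

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ns.poisson_spikes(TimeSeries(-np.ones((1, 10)), 1.0))

    def test_count_kolmogorov_consistent_with_poisson(self):
        r, T = 0.02, 50_000
        rates = TimeSeries(np.full((1, T), r), 1.0)
        counts = [len(ns.poisson_spikes(rates, seed=s)) for s in range(40)]
        # Bernoulli(r*dt) per bin: Binomial(T, r) ~ Poisson(rT) at r*dt << 1
        ks = stats.kstest(counts, stats.poisson(mu=r * T).cdf)
        assert ks.pvalue > 0.01

    def test_round_trip_through_smoothing(self):
        r, T = 0.05, 200_000
        rates = TimeSeries(np.full((1, T), r), 1.0)
        events = ns.poisson_spikes(rates, seed=1)
        ts = spikes_to_rate(events, dt=2.0, kernel_width=10.0, unit_ids=["u0"],
                            t_stop=T)
        se = np.sqrt(len(events)) / T
        assert abs(ts.values.mean() - r) < 3 * se


def test_output_seq_exceeds_input_seq_for_random_symmetric_net():
    """Spurious sequences: non-sequential input, sequential output."""
    from conftest import measure_denoised
    from seqnet import connectivity as cn

    S = cn.make_input_covariance("fixed_corr", N=20, seed=0)
    W = cn.random_ensemble("symmetric", 20, seed=1)
    model = ns.InputModel(mu=0.1, Sigma_in=S, tau_in=15.0)
    cfg = ns.NetworkConfig(T=60_000)
    v, _, xi = ns.run_network(W, model, cfg, seed=2)
    seq_out = measure_denoised(v, max_lag=200.0, lag_step=2.0)
    seq_in = measure_denoised(xi, max_lag=200.0, lag_step=2.0)
    assert (np.isnan(seq_in) or seq_in == 0.0)
    assert seq_out > 0.02
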