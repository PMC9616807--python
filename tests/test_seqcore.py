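"""Lagged covariance estimation, Gamma decomposition, noise floor, seq index."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg, stats

from seqnet import seqcore as sc
from seqnet import synthdata as sd
from seqnet.timeseries import TimeSeries

from conftest import measure_denoised


def brute_force_covariance(X, offs, L, norm):
    """Direct double-loop implementation of the lagged covariance sums."""
    N, T = X.shape
    D = X - X.mean(axis=1, keepdims=True)
    C = np.zeros((N, N, len(offs)))
    for j in range(N):
        for k in range(N):
            for si, s in enumerate(offs):
                acc = 0.0
                for t in range(L, T - L):
                    acc += D[j, t + s] * D[k, t]
                C[j, k, si] = acc / norm
    return C


class TestLaggedCovariance:
    def test_matches_brute_force_double_loop(self, rng):
        X = rng.standard_normal((2, 200))
        cov = sc.estimate_lagged_covariance(TimeSeries(X, 1.0), max_lag=5,
                                            lag_step=1.0, n_epochs=1)
        offs = np.arange(-5, 6)
        expected = brute_force_covariance(X, offs, 5, 200 - 10)
        np.testing.assert_allclose(cov.C, expected, atol=1e-12)

    def test_constant_series_gives_zero(self):
        X = np.ones((3, 500)) * np.array([[1.0], [2.0], [-1.0]])
        cov = sc.estimate_lagged_covariance(TimeSeries(X, 1.0), max_lag=10,
                                            lag_step=1.0, n_epochs=2)
        np.testing.assert_allclose(cov.C, 0.0, atol=1e-14)

    def test_white_noise_autocovariance(self, rng):
        v = 2.5
        X = rng.normal(0, np.sqrt(v), (1, 40_000))
        cov = sc.estimate_lagged_covariance(TimeSeries(X, 1.0), max_lag=10,
                                            lag_step=1.0, n_epochs=4)
        i0 = np.where(cov.lags == 0)[0][0]
        se = v / np.sqrt(10_000)
        assert abs(cov.C[0, 0, i0] - v) < 3 * np.sqrt(2) * se
        off = np.delete(cov.C[0, 0], i0)
        assert np.all(np.abs(off) < 5 * se)

    def test_delayed_copy_peaks_at_minus_delay(self, rng):
        x = rng.standard_normal(4000)
        d = 7
        X = np.vstack([x, np.roll(x, d)])   # unit 2 trails unit 1 by d steps
        cov = sc.estimate_lagged_covariance(TimeSeries(X, 1.0), max_lag=20,
                                            lag_step=1.0, n_epochs=2)
        # C_12(s) = cov(X1(t+s), X2(t)) peaks where t+s aligns with t-d
        assert cov.lags[np.argmax(cov.C[0, 1])] == -d
        assert cov.lags[np.argmax(cov.C[1, 0])] == +d

    def test_epoch_mean_is_average_of_epoch_estimates(self, small_series):
        cov = sc.estimate_lagged_covariance(small_series, max_lag=20,
                                            lag_step=2.0, n_epochs=5)
        np.testing.assert_allclose(cov.C, cov.epoch_estimates.mean(axis=0))
        assert cov.n_epochs == 5

    def test_stationarity_identity_up_to_edge_effects(self, small_series):
        cov = sc.estimate_lagged_covariance(small_series, max_lag=20,
                                            lag_step=2.0, n_epochs=2)
        order = np.argsort(cov.lags)
        C = cov.C[:, :, order]
        rev_T = C[:, :, ::-1].transpose(1, 0, 2)
        scale = np.abs(C).max()
        assert np.abs(C - rev_T).max() < 0.05 * scale

    def test_short_epoch_rejected_with_minimum_length(self, small_series):
        with pytest.raises(ValueError, match="at least"):
            sc.estimate_lagged_covariance(small_series, max_lag=300,
                                          lag_step=2.0, n_epochs=10)

    def test_lag_grid_must_divide_dt(self, small_series):
        with pytest.raises(ValueError, match="sampling step"):
            sc.estimate_lagged_covariance(small_series, max_lag=5,
                                          lag_step=0.5)


class TestGamma:
    def test_hand_checked_layout(self):
        # N=2, S=3 with distinct entries: row index is i + j*N
        C = np.arange(12, dtype=float).reshape(2, 2, 3)
        G = sc.build_gamma(C)
        assert G.shape == (4, 3)
        for i, j in itertools.product(range(2), range(2)):
            np.testing.assert_array_equal(G[i + 2 * j], C[i, j])

    def test_round_trip_and_norm(self, rng):
        C = rng.standard_normal((5, 5, 7))
        G = sc.build_gamma(C)
        np.testing.assert_array_equal(sc.unflatten_gamma(G, 5), C)
        assert np.isclose(np.linalg.norm(G), np.linalg.norm(C))


class TestSpectrum:
    def test_rank_one_even_structure(self):
        lags = np.arange(-3.0, 4.0)
        f = np.exp(-np.abs(lags))            # even lag profile
        a = np.array([1.0, -2.0, 0.5, 0.3])  # N=2 spatial part
        G = np.outer(a, f)
        spec = sc.decompose_spectrum(G, lags)
        nz = spec.sigmas > 1e-12
        assert nz.sum() == 1
        assert spec.parities[nz][0] == "sym"

    def test_construct_then_recover(self, rng):
        lags = np.arange(-5.0, 6.0)
        f1 = np.exp(-lags**2 / 4.0)          # even
        f2 = lags * np.exp(-np.abs(lags))    # odd
        f1 /= np.linalg.norm(f1)
        f2 /= np.linalg.norm(f2)
        a1 = rng.standard_normal(9)
        a2 = rng.standard_normal(9)
        a2 -= a1 * (a1 @ a2) / (a1 @ a1)
        a1 /= np.linalg.norm(a1)
        a2 /= np.linalg.norm(a2)
        s1, s2 = 3.0, 1.5
        G = s1 * np.outer(a1, f1) + s2 * np.outer(a2, f2)
        spec = sc.decompose_spectrum(G, lags)
        nz = spec.sigmas > 1e-10
        assert nz.sum() == 2
        np.testing.assert_allclose(sorted(spec.sigmas[nz]), [s2, s1], atol=1e-10)
        got = dict(zip(np.round(spec.sigmas[nz], 6), spec.parities[nz]))
        assert got[3.0] == "sym" and got[1.5] == "asym"

    def test_energy_identity(self, rng):
        lags = np.arange(-4.0, 5.0)
        G = rng.standard_normal((16, 9))
        spec = sc.decompose_spectrum(G, lags)
        assert np.isclose(np.sum(spec.sigmas**2), np.linalg.norm(G) ** 2)

    def test_temporal_components_have_definite_parity(self, small_series):
        cov = sc.estimate_lagged_covariance(small_series, max_lag=20,
                                            lag_step=2.0)
        spec = sc.decompose_spectrum(sc.build_gamma(cov), cov.lags,
                                     compute_components=True)
        keep = spec.sigmas > 1e-8 * spec.sigmas[0]
        for f, par in zip(spec.temporal_components[keep], spec.parities[keep]):
            mirrored = f[::-1]
            if par == "sym":
                np.testing.assert_allclose(f, mirrored, atol=1e-8)
            else:
                np.testing.assert_allclose(f, -mirrored, atol=1e-8)

    def test_asymmetric_grid_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sc.decompose_spectrum(np.zeros((4, 3)), np.array([-1.0, 0.0, 2.0]))


class TestNoiseFloor:
    def test_identical_epochs_give_zero_floor(self, rng):
        sig = rng.standard_normal((1, 3, 3, 5))
        cov = sc.LaggedCovariance(C=sig[0], lags=np.arange(-2.0, 3.0),
                                  epoch_estimates=np.repeat(sig, 6, axis=0))
        floor = sc.estimate_noise_floor(cov)
        assert floor.sample_sigmas.max() == 0.0
        assert floor.mu == 0.0

    def test_single_epoch_rejected(self, small_series):
        cov = sc.estimate_lagged_covariance(small_series, max_lag=10,
                                            lag_step=2.0, n_epochs=1)
        with pytest.raises(ValueError, match="2 epochs"):
            sc.estimate_noise_floor(cov)

    def test_monte_carlo_consistency(self, rng):
        """Pooled pair-difference draws match the noise of an M-epoch mean."""
        N, S, M = 5, 11, 10
        lags = np.arange(-5.0, 6.0)
        sig = rng.standard_normal((N, N, S))
        sd_noise = 0.4
        est = sig[None] + rng.normal(0, sd_noise, (M, N, N, S))
        cov = sc.LaggedCovariance(C=est.mean(0), lags=lags, epoch_estimates=est)
        floor = sc.estimate_noise_floor(cov)
        draws = []
        for _ in range(40):
            n = rng.normal(0, sd_noise, (M, N, N, S)).mean(0)
            draws.append(linalg.svdvals(sc.build_gamma(n)))
        oracle = np.concatenate(draws)
        a = rng.choice(floor.sample_sigmas, 200, replace=False)
        b = rng.choice(oracle, 200, replace=False)
        assert stats.mannwhitneyu(a, b).pvalue > 0.01

    def test_doubling_epochs_shrinks_floor_by_sqrt2(self, rng):
        N, S = 4, 9
        lags = np.arange(-4.0, 5.0)
        sig = rng.standard_normal((N, N, S))

        def floor_mu(M):
            est = sig[None] + rng.normal(0, 0.5, (M, N, N, S))
            cov = sc.LaggedCovariance(C=est.mean(0), lags=lags,
                                      epoch_estimates=est)
            return sc.estimate_noise_floor(cov).mu

        ratio = floor_mu(8) / floor_mu(16)
        assert abs(ratio - np.sqrt(2)) < 0.25


class TestSequentialityRaw:
    def test_symmetric_covariance_gives_zero(self, rng):
        lags = np.arange(-3.0, 4.0)
        half = rng.standard_normal((3, 3, 3))
        C = np.concatenate([half[:, :, ::-1], rng.standard_normal((3, 3, 1)),
                            half], axis=2)
        cov = sc.LaggedCovariance(C=C, lags=lags)
        assert sc.sequentiality_raw(cov) == 0.0

    def test_perfect_sequence_reaches_one(self):
        ts = sd.perfect_sequence(21, 50)
        cov = sc.estimate_lagged_covariance(ts, max_lag=10, lag_step=1.0,
                                            n_epochs=1)
        assert abs(sc.sequentiality_raw(cov) - 1.0) < 1e-6

    def test_matches_brute_force_summation(self, rng):
        C = rng.standard_normal((2, 2, 3))
        lags = np.array([-1.0, 0.0, 1.0])
        cov = sc.LaggedCovariance(C=C, lags=lags)
        num = den = 0.0
        for j in range(2):
            for k in range(2):
                for si, s in enumerate(lags):
                    smi = np.where(lags == -s)[0][0]
                    num += (C[j, k, si] - C[j, k, smi]) ** 2
                    den += (C[j, k, si] + C[j, k, smi]) ** 2
        assert np.isclose(sc.sequentiality_raw(cov), np.sqrt(num / den))

    def test_zero_denominator_is_undefined(self):
        lags = np.array([-1.0, 0.0, 1.0])
        C = np.zeros((2, 2, 3))
        C[0, 1, 0], C[0, 1, 2] = 1.0, -1.0   # purely odd
        with pytest.warns(sc.UndefinedSequentiality):
            assert np.isnan(sc.sequentiality_raw(
                sc.LaggedCovariance(C=C, lags=lags)))

    def test_spectrum_energies_reproduce_ratio_exactly(self, small_series):
        cov = sc.estimate_lagged_covariance(small_series, max_lag=20,
                                            lag_step=2.0)
        spec = sc.decompose_spectrum(sc.build_gamma(cov), cov.lags)
        asym = spec.parities == "asym"
        ratio = np.sqrt(np.sum(spec.sigmas[asym] ** 2)
                        / np.sum(spec.sigmas[~asym] ** 2))
        assert abs(ratio - sc.sequentiality_raw(cov)) < 1e-10


class TestSequentialityDenoised:
    def _spectrum(self, sigmas, parities, lags=None):
        return sc.SeqSpectrum(sigmas=np.asarray(sigmas, float),
                              parities=np.asarray(parities, dtype=str),
                              lags=lags if lags is not None
                              else np.array([-1.0, 0.0, 1.0]))

    def test_subfloor_asym_components_removed(self):
        spec = self._spectrum([10.0, 0.1, 0.05], ["sym", "asym", "asym"])
        floor = sc.NoiseFloor(sample_sigmas=np.array([0.1]), mu=0.1, sd=0.05,
                              n_epochs=10)
        assert sc.sequentiality_denoised(spec, floor, multiplier=7.0) == 0.0

    def test_no_survivors_is_undefined(self):
        spec = self._spectrum([0.1, 0.05], ["sym", "asym"])
        floor = sc.NoiseFloor(sample_sigmas=np.array([1.0]), mu=1.0, sd=0.2,
                              n_epochs=10)
        with pytest.warns(sc.UndefinedSequentiality):
            assert np.isnan(sc.sequentiality_denoised(spec, floor))

    def test_surviving_set_shrinks_with_multiplier(self, small_series):
        cov = sc.estimate_lagged_covariance(small_series, max_lag=20,
                                            lag_step=2.0)
        spec = sc.decompose_spectrum(sc.build_gamma(cov), cov.lags)
        floor = sc.estimate_noise_floor(cov)
        prev = None
        for m in (0.0, 1.0, 3.0, 7.0, 20.0):
            surv = set(np.where(spec.sigmas >= floor.threshold(m))[0])
            if prev is not None:
                assert surv <= prev
            prev = surv

    def test_pure_noise_never_spuriously_positive(self):
        for seed in range(12):
            ts = sd.white_noise(8, 10_000, seed=seed)
            s = measure_denoised(ts, max_lag=50, lag_step=2.0)
            assert np.isnan(s) or s == 0.0


class TestInvariances:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_permutation_time_reversal_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        n = 3
        mix = np.eye(n) + 0.5 * rng.standard_normal((n, n))
        X = mix @ rng.standard_normal((n, 3000))
        # add lagged coupling so seq_raw is typically nonzero
        X[1, 5:] += 0.5 * X[0, :-5]
        base = TimeSeries(X, 1.0)

        def raw(ts):
            cov = sc.estimate_lagged_covariance(ts, max_lag=10, lag_step=1.0,
                                                n_epochs=2)
            return sc.sequentiality_raw(cov)

        ref = raw(base)
        perm = rng.permutation(n)
        assert np.isclose(raw(TimeSeries(X[perm], 1.0)), ref, atol=1e-12)
        assert np.isclose(raw(TimeSeries(X[:, ::-1], 1.0)), ref, atol=1e-12)
        assert np.isclose(raw(TimeSeries(3.7 * X, 1.0)), ref, atol=1e-12)

    def test_denoised_invariant_under_permutation(self, rng):
        X = rng.standard_normal((4, 8000))
        X[2, 3:] += 0.6 * X[0, :-3]
        ref = measure_denoised(TimeSeries(X, 1.0), max_lag=20, lag_step=2.0)
        perm = measure_denoised(TimeSeries(X[rng.permutation(4)], 1.0),
                                max_lag=20, lag_step=2.0)
        assert np.isclose(ref, perm, atol=1e-9, equal_nan=True)


class TestEstimatorFront:
    def test_fit_exposes_attributes_and_score(self, small_series):
        est = sc.SequentialityAnalysis(max_lag=20, lag_step=2.0)
        est.fit(small_series)
        assert 0.0 <= est.seq_raw_
        assert est.spectrum_.sigmas.shape == est.spectrum_.parities.shape
        assert est.noise_floor_.n_epochs == 10
        assert est.score() == est.seq_ or (np.isnan(est.seq_)
                                           and np.isnan(est.score()))

    def test_array_input_equivalent_to_timeseries(self, small_series):
        a = sc.SequentialityAnalysis(max_lag=20, lag_step=2.0, dt=1.0)
        b = sc.SequentialityAnalysis(max_lag=20, lag_step=2.0, dt=1.0)
        a.fit(small_series)
        b.fit(small_series.values.T)
        np.testing.assert_allclose(a.covariance_.C, b.covariance_.C)

    def test_sklearn_params_round_trip(self):
        est = sc.SequentialityAnalysis(multiplier=5.0)
        params = est.get_params()
        assert params["multiplier"] == 5.0
        est.set_params(multiplier=3.0)
        assert est.multiplier == 3.0
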