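import numpy as np
import pytest

from seqnet.timeseries import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng):
    """Correlated 4-unit series long enough for 2-epoch covariance estimates."""
    n, t = 4, 4000
    base = rng.standard_normal((n, t))
    mix = np.eye(n) + 0.3 * rng.standard_normal((n, n))
    return TimeSeries(values=mix @ base, dt=1.0)


def measure_denoised(ts, **kw):
    """Denoised sequentiality with warnings silenced (NaN = undefined)."""
    import warnings

    from seqnet import seqcore as sc

    cov = sc.estimate_lagged_covariance(ts, **kw)
    spec = sc.decompose_spectrum(sc.build_gamma(cov), cov.lags)
    floor = sc.estimate_noise_floor(cov)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sc.UndefinedSequentiality)
        return sc.sequentiality_denoised(spec, floor)
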