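"""Distribution machinery: SST, BCPE, normal, and their links."""

import numpy as np
import pytest
from scipy import integrate, stats

from normtrade import (
    DistParams,
    SST,
    density,
    cdf,
    quantile,
    sample,
    link_apply,
    link_invert,
)

SST_PARAMS = [
    DistParams(10, 3, 0.7, 5),
    DistParams(0, 1, 1.0, 4),
    DistParams(-5, 2.5, 1.6, 12),
    DistParams(22, 5.5, 0.78, 6.5),
]
BCPE_PARAMS = [
    DistParams(100, 0.08, 1.5, 3.0),
    DistParams(50, 0.1, -0.5, 4.0),
    DistParams(50, 0.1, 0.0, 2.0),
    DistParams(120, 0.05, 1.0, 1.5),
]


@pytest.mark.parametrize(
    "family,p,support",
    [("SST", p, (-np.inf, np.inf)) for p in SST_PARAMS]
    + [("BCPE", p, (1e-9, 2000)) for p in BCPE_PARAMS]
    + [("normal", DistParams(3, 2), (-np.inf, np.inf))],
)
def test_density_integrates_to_one(family, p, support):
    val, _ = integrate.quad(
        lambda x: density(family, x, p), support[0], support[1], limit=300
    )
    assert val == pytest.approx(1.0, abs=1e-8)


def test_sst_normal_limit_pointwise():
    """SST(mu, sigma, 1, 1e6) matches the normal density within 1e-6."""
    sst = SST()
    mu, sigma = 3.0, 2.0
    x = np.linspace(mu - 5 * sigma, mu + 5 * sigma, 401)
    diff = sst.pdf(x, mu, sigma, 1.0, 1e6) - stats.norm.pdf(x, mu, sigma)
    assert np.max(np.abs(diff)) < 1e-6
    assert sst.cdf(mu + 1.959964 * sigma, mu, sigma, 1.0, 1e6) == pytest.approx(
        0.975, abs=1e-6
    )


@pytest.mark.parametrize("nu", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("tau", [2.5, 5.0, 50.0])
def test_sst_mean_sd_equal_mu_sigma(nu, tau):
    """Numeric mean and SD by quadrature equal mu and sigma (contract)."""
    p = DistParams(10, 3, nu, tau)
    mean, _ = integrate.quad(
        lambda x: x * density("SST", x, p), -np.inf, np.inf, limit=400
    )
    var, _ = integrate.quad(
        lambda x: (x - 10.0) ** 2 * density("SST", x, p), -np.inf, np.inf, limit=400
    )
    assert mean == pytest.approx(10.0, abs=1e-5)
    assert np.sqrt(var) == pytest.approx(3.0, abs=1e-5)


@pytest.mark.parametrize(
    "family,p",
    [("SST", p) for p in SST_PARAMS]
    + [("BCPE", p) for p in BCPE_PARAMS]
    + [("normal", DistParams(3, 2))],
)
def test_quantile_cdf_round_trip(family, p):
    q = np.linspace(0.01, 0.99, 99)
    x = quantile(family, q, p)
    assert np.all(np.diff(x) > 0), "quantile must be monotone in q"
    assert np.max(np.abs(cdf(family, x, p) - q)) < 1e-8


def test_symmetric_sst_centered_at_mu():
    p = DistParams(12.0, 3.0, 1.0, 8.0)
    assert cdf("SST", 12.0, p) == pytest.approx(0.5, abs=1e-12)
    assert quantile("SST", 0.5, p) == pytest.approx(12.0, abs=1e-9)


def test_bcpe_median_near_mu():
    p = DistParams(100, 0.08, 1.5, 3.0)
    assert quantile("BCPE", 0.5, p) == pytest.approx(100.0, rel=1e-6)


def test_sampling_reproducible_and_consistent():
    p = DistParams(0, 1, 1.0, 1e6)
    s1 = sample("SST", p, 1000, seed=7)
    s2 = sample("SST", p, 1000, seed=7)
    np.testing.assert_array_equal(s1, s2)
    big = sample("SST", p, 100_000, seed=11)
    assert abs(big.mean()) < 3.0 / np.sqrt(100_000)
    ks = stats.kstest(big, lambda x: cdf("SST", x, p)).statistic
    assert ks < 0.01


def test_bcpe_sampling_matches_cdf():
    p = DistParams(100, 0.08, 1.5, 3.0)
    s = sample("BCPE", p, 50_000, seed=5)
    assert np.all(s > 0)
    ks = stats.kstest(s, lambda x: cdf("BCPE", x, p)).statistic
    assert ks < 0.01


@pytest.mark.parametrize(
    "link,value,eta",
    [("log", 1.0, 0.0), ("log-2", 3.0, 0.0), ("identity", 12.3, 12.3)],
)
def test_link_examples_and_round_trip(link, value, eta):
    assert link_apply(link, value) == pytest.approx(eta)
    assert link_invert(link, link_apply(link, value)) == pytest.approx(value)


def test_link_domain_errors():
    with pytest.raises(ValueError):
        link_apply("log", -1.0)
    with pytest.raises(ValueError):
        link_apply("log-2", 2.0)


def test_invalid_parameters_raise():
    with pytest.raises(ValueError):
        density("SST", 0.0, DistParams(0, 1, 1.0, 2.0))  # tau <= 2
    with pytest.raises(ValueError):
        density("SST", 0.0, DistParams(0, -1, 1.0, 5.0))  # sigma <= 0
    with pytest.raises(ValueError):
        density("SST", 0.0, DistParams(0, 1, -0.5, 5.0))  # nu <= 0
    with pytest.raises(ValueError):
        density("BCPE", -1.0, DistParams(100, 0.1, 1.0, 2.0))  # x <= 0
    with pytest.raises(ValueError):
        quantile("SST", 1.2, DistParams(0, 1, 1, 5))
    with pytest.raises(ValueError):
        sample("SST", DistParams(0, 1, 1, 5), 0)


def test_dist_params_serialization():
    p = DistParams(10, 3, 0.7, 5)
    d = p.as_dict("SST")
    assert d == {"family": "SST", "mu": 10, "sigma": 3, "nu": 0.7, "tau": 5}
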