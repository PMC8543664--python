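"""Factorial population models and normative-sample generation."""

import io

import numpy as np
import pytest
from numpy.polynomial import polynomial as npoly
from scipy import special, stats

from normtrade import (
    DistParams,
    all_populations,
    build_population,
    get_family,
    population_params,
    population_score_at_z,
    sample_norm_data,
)
from normtrade.population import NormativeSample, _scale_age


def test_eight_distinct_populations():
    pops = all_populations()
    assert len(pops) == 8
    assert len({p.flags for p in pops}) == 8
    assert len({p.name for p in pops}) == 8
    # pairwise distinguishable by at least one parameter curve
    curves = [tuple(sorted((k, tuple(v)) for k, v in p.curves.items())) for p in pops]
    assert len(set(curves)) == 8


def test_most_restricted_corner_is_linear_homoscedastic_normal():
    pop = build_population(linear_mu=True, homoscedastic=True, normal=True)
    assert pop.name == "Li-HoNo"
    assert pop.family == "normal"
    assert len(pop.curves["mu"]) == 2
    assert len(pop.curves["sigma"]) == 1
    assert "nu" not in pop.curves and "tau" not in pop.curves


def test_homoscedastic_flag_makes_sigma_constant():
    pop = build_population(homoscedastic=True)
    p5 = population_params(pop, 5.0)
    p21 = population_params(pop, 21.0)
    assert p5.sigma == pytest.approx(p21.sigma, rel=1e-12)


def test_heteroscedastic_default_varies_sigma(ids_pop):
    assert population_params(ids_pop, 5.0).sigma != pytest.approx(
        population_params(ids_pop, 21.0).sigma, rel=1e-3
    )


def test_linear_mu_midpoint(ids_pop):
    pop = build_population(linear_mu=True)
    mu = [population_params(pop, a).mu for a in (5.0, 13.0, 21.0)]
    assert mu[1] == pytest.approx((mu[0] + mu[2]) / 2.0, abs=1e-10)


def test_curve_evaluation_matches_direct_polyval(ids_pop):
    ages = np.array([5.0, 9.7, 13.0, 18.2, 21.0])
    params = ids_pop.params_at(ages)
    u = _scale_age(ages)
    np.testing.assert_allclose(
        params["mu"], npoly.polyval(u, np.asarray(ids_pop.curves["mu"])), rtol=1e-14
    )
    np.testing.assert_allclose(
        params["sigma"],
        np.exp(npoly.polyval(u, np.asarray(ids_pop.curves["sigma"]))),
        rtol=1e-14,
    )


def test_age_out_of_range_raises(ids_pop):
    with pytest.raises(ValueError):
        population_params(ids_pop, 25.0)


def test_sample_ages_evenly_spaced_and_deterministic(ids_pop):
    s1 = sample_norm_data(ids_pop, 500, seed=123)
    s2 = sample_norm_data(ids_pop, 500, seed=123)
    np.testing.assert_array_equal(s1.scores, s2.scores)
    np.testing.assert_allclose(s1.ages, np.linspace(5, 21, 500), rtol=1e-14)
    assert np.all(np.isfinite(s1.scores))
    with pytest.raises(ValueError):
        sample_norm_data(ids_pop, 1)


def test_conditional_draws_mean_matches_mu(ids_pop):
    """Repeated draws at a fixed age have mean mu(age) (CLT bound)."""
    age = 13.0
    p = ids_pop.params_at(np.full(100_000, age))
    fam = get_family(ids_pop.family)
    draws = fam.rvs(**p, size=100_000, rng=909)
    se = p["sigma"][0] / np.sqrt(100_000)
    assert draws.mean() == pytest.approx(p["mu"][0], abs=3 * se)


def test_normal_population_draws_pass_normality():
    pop = build_population(normal=True, homoscedastic=True, linear_mu=True)
    age = 8.0
    p = pop.dist_params(age)
    draws = get_family("normal").rvs(p.mu, p.sigma, size=100_000, rng=5)
    ks = stats.kstest(draws, "norm", args=(p.mu, p.sigma)).statistic
    assert ks < 0.02


def test_score_at_z_round_trip(ids_pop):
    ages = np.array([5.0, 13.0, 21.0])
    for z in (-3.0, -1.2, 0.0, 2.5, 3.0):
        s = population_score_at_z(ids_pop, ages, np.full(3, z))
        p = ids_pop.cdf(ages, s)
        np.testing.assert_allclose(special.ndtri(p), z, atol=1e-8)
    s_lo = population_score_at_z(ids_pop, 13.0, -3.0)
    s_hi = population_score_at_z(ids_pop, 13.0, 3.0)
    assert s_lo < s_hi


def test_score_at_z_zero_is_mean_for_normal_population():
    pop = build_population(normal=True)
    assert population_score_at_z(pop, 13.0, 0.0) == pytest.approx(
        pop.dist_params(13.0).mu
    )


def test_population_json_round_trip(ids_pop):
    d = ids_pop.to_dict()
    pop2 = type(ids_pop).from_dict(d)
    assert pop2.curves == {k: list(map(float, v)) for k, v in ids_pop.curves.items()}
    assert pop2.name == ids_pop.name


def test_normative_sample_csv_round_trip(tmp_path, ids_pop):
    s = sample_norm_data(ids_pop, 50, seed=42, replicate_id=3)
    path = tmp_path / "sample.csv"
    s.to_csv(path)
    s2 = NormativeSample.from_csv(path)
    np.testing.assert_allclose(s2.scores, s.scores, rtol=1e-12)
    assert s2.population_id == ids_pop.name
    assert s2.replicate_id == 3
    assert s2.seed == 42
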