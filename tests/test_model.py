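"""Penalized distributional-regression engine and model selection."""

import numpy as np
import pytest

from normtrade import (
    DistParams,
    ModelSpec,
    NormingModel,
    NormingResults,
    TermSpec,
    gaic,
    sample,
    select_lambda,
    select_model_bic,
    enumerate_polynomial_grid,
)
from normtrade.model import fit as fit_fn, predict_params


def _normal_spec(mu_term=None, tol=1e-12):
    return ModelSpec(
        family="normal",
        terms={"mu": mu_term or TermSpec(), "sigma": TermSpec()},
        tolerance=tol,
    )


def test_intercept_normal_matches_closed_form_ml(ages_500):
    rng = np.random.default_rng(12)
    y = rng.normal(7.5, 2.3, ages_500.size)
    res = NormingModel(ages_500, y, _normal_spec()).fit()
    p = res.predict_dist_params(13.0)
    assert p.mu == pytest.approx(y.mean(), abs=1e-8)
    assert p.sigma == pytest.approx(y.std(), abs=1e-8)  # ML (1/n) SD
    assert res.converged and not res.failed
    assert res.edf_total == pytest.approx(2.0)


def test_linear_normal_recovers_slope_against_ols():
    rng = np.random.default_rng(99)
    ages = np.linspace(5, 21, 2000)
    y = 2.0 + 3.0 * ages + rng.normal(0, 1.0, 2000)
    res = NormingModel(ages, y, _normal_spec(TermSpec(kind="linear"))).fit()
    x = np.column_stack([np.ones_like(ages), ages])
    ols = np.linalg.lstsq(x, y, rcond=None)[0]
    assert res.params["mu"][1] == pytest.approx(ols[1], abs=1e-6)
    assert abs(res.params["mu"][1] - 3.0) < 0.1


def test_sst_intercept_recovers_parameters_within_3se():
    true = DistParams(20, 5, 0.8, 6)
    n = 10_000
    y = sample("SST", true, n, seed=31)
    res = fit_fn((np.linspace(5, 21, n), y), ModelSpec(family="SST"))
    assert not res.failed
    p = res.predict_dist_params(13.0)
    # asymptotic SEs: mu ~ sigma/sqrt(n); others are wide for shape params
    assert p.mu == pytest.approx(true.mu, abs=3 * true.sigma / np.sqrt(n))
    assert p.sigma == pytest.approx(true.sigma, rel=0.05)
    assert p.nu == pytest.approx(true.nu, rel=0.15)
    assert 3.0 < p.tau < 12.0


def test_gaic_definitions(ids_sample):
    spec = ModelSpec(family="SST")
    res = fit_fn(ids_sample.as_tuple(), spec)
    assert gaic(res, 0.0) == pytest.approx(res.deviance)
    n = len(ids_sample)
    assert gaic(res, np.log(n)) == pytest.approx(res.bic)
    assert gaic(res, 5.0) > gaic(res, 2.0)  # increasing in k for edf > 0


def test_gaic_on_failed_fit_raises(ids_sample):
    failed = NormingResults._failed(
        NormingModel(*ids_sample.as_tuple(), ModelSpec(family="SST")), "boom"
    )
    with pytest.raises(ValueError):
        gaic(failed, 2.0)


def test_select_lambda_no_auto_terms_is_noop(ids_sample):
    spec = ModelSpec(family="SST")
    assert select_lambda(ids_sample.as_tuple(), spec) is spec


def test_select_lambda_beats_grid_endpoints():
    rng = np.random.default_rng(5)
    ages = np.linspace(5, 21, 400)
    y = np.sin((ages - 5) / 3.0) * 4 + rng.normal(0, 1.0, 400)
    spec = ModelSpec(
        family="normal",
        terms={"mu": TermSpec(kind="pspline", lam="auto"), "sigma": TermSpec()},
    )
    chosen = select_lambda((ages, y), spec, k=5.0)
    lam_star = chosen.terms["mu"].lam
    assert isinstance(lam_star, float)

    def gaic_at(lam):
        s = ModelSpec(
            family="normal",
            terms={"mu": TermSpec(kind="pspline", lam=lam), "sigma": TermSpec()},
        )
        return fit_fn((ages, y), s).gaic(5.0)

    g_star = gaic_at(lam_star)
    assert g_star <= gaic_at(1e-4) + 1e-6
    assert g_star <= gaic_at(1e6) + 1e-6


def test_auto_lambda_on_noiseless_line_gives_edf_two():
    ages = np.linspace(5, 21, 300)
    y = 1.0 + 0.5 * ages + np.random.default_rng(2).normal(0, 1e-3, 300)
    spec = ModelSpec(
        family="normal",
        terms={"mu": TermSpec(kind="pspline", lam="auto"), "sigma": TermSpec()},
    )
    res = fit_fn((ages, y), spec)
    assert res.edf["mu"] == pytest.approx(2.0, abs=0.1)


def test_candidate_grid_has_648_models():
    grid = enumerate_polynomial_grid()
    assert len(grid) == 648
    labels = {s.label for s in grid}
    assert len(labels) == 648  # all distinct


def test_select_model_bic_contract(ids_sample):
    degrees = [(0, 0, 0, 0), (2, 1, 0, 0), (4, 2, 1, 0)]
    cands = [
        ModelSpec(
            family="SST",
            terms={
                "mu": TermSpec(kind="poly", degree=dm),
                "sigma": TermSpec(kind="poly", degree=ds),
                "nu": TermSpec(kind="poly", degree=dn),
                "tau": TermSpec(kind="poly", degree=dt),
            },
        )
        for dm, ds, dn, dt in degrees
    ]
    best_spec, best_res = select_model_bic(ids_sample.as_tuple(), cands)
    n = len(ids_sample)
    # recompute BIC manually on the winner
    assert best_res.bic == pytest.approx(
        -2.0 * best_res.llf + np.log(n) * best_res.edf_total
    )
    for c in cands:
        res = fit_fn(ids_sample.as_tuple(), c)
        assert best_res.bic <= res.bic + 1e-9
    single_spec, _ = select_model_bic(ids_sample.as_tuple(), [cands[0]])
    assert single_spec is cands[0]
    with pytest.raises(ValueError):
        select_model_bic(ids_sample.as_tuple(), [])


def test_predict_params_contracts(ids_sample):
    res_const = fit_fn(ids_sample.as_tuple(), ModelSpec(family="SST"))
    p5 = res_const.predict_dist_params(5.0)
    p21 = res_const.predict_dist_params(21.0)
    assert p5 == p21  # intercept-only: constant in age
    assert p5.tau > 2.0

    ages = np.linspace(5, 21, 200)
    y = 2.0 + 3.0 * ages
    res_lin = fit_fn((ages, y + np.random.default_rng(0).normal(0, 1e-6, 200)),
                     _normal_spec(TermSpec(kind="linear")))
    mu = res_lin.predict_params(np.array([8.0, 15.5]))["mu"]
    assert np.allclose(mu, 2.0 + 3.0 * np.array([8.0, 15.5]), atol=1e-4)
    with pytest.raises(ValueError):
        res_lin.predict_params([np.nan])


def test_refit_is_bit_reproducible(ids_sample):
    spec = ModelSpec(
        family="SST",
        terms={"mu": TermSpec(kind="pspline", lam="auto"), "sigma": TermSpec(),
               "nu": TermSpec(), "tau": TermSpec()},
    )
    r1 = fit_fn(ids_sample.as_tuple(), spec)
    r2 = fit_fn(ids_sample.as_tuple(), spec)
    for p in r1.params:
        np.testing.assert_array_equal(r1.params[p], r2.params[p])
    assert r1.llf == r2.llf


def test_curve_recovery_error_decreases_with_n(ids_pop):
    """Fitting the true structure recovers the mu curve better at larger n."""
    from normtrade import sample_norm_data, build_estimation_spec

    spec = build_estimation_spec(ids_pop, "True[linear/splines]")
    ages_eval = np.linspace(5, 21, 101)
    mu_true = ids_pop.params_at(ages_eval)["mu"]
    maes = {}
    for n in (500, 2000):
        s = sample_norm_data(ids_pop, n, seed=77)
        res = NormingModel(s.ages, s.scores, spec).fit()
        mu_hat = res.predict_params(ages_eval)["mu"]
        maes[n] = np.mean(np.abs(mu_hat - mu_true))
    assert maes[2000] < maes[500]


def test_max_iterations_cap_returns_coefficients(ids_sample):
    spec = ModelSpec(family="SST", max_iterations=2)
    res = fit_fn(ids_sample.as_tuple(), spec)
    assert not res.failed
    assert not res.converged
    assert res.iterations == 2
    assert res.params is not None  # cap-limited fits are still usable


def test_bcpe_requires_positive_offset_scores():
    ages = np.linspace(5, 21, 50)
    scores = np.full(50, -200.0)
    with pytest.raises(ValueError):
        NormingModel(ages, scores, ModelSpec(family="BCPE", offset=100.0))


def test_results_json_round_trip(tmp_path, ids_sample):
    spec = ModelSpec(
        family="SST",
        terms={"mu": TermSpec(kind="pspline", lam="auto"), "sigma": TermSpec(),
               "nu": TermSpec(), "tau": TermSpec()},
    )
    res = fit_fn(ids_sample.as_tuple(), spec)
    path = tmp_path / "fit.json"
    res.save(path)
    loaded = NormingResults.load(path)
    ages = np.array([6.5, 13.0, 19.5])
    for p, v in res.predict_params(ages).items():
        np.testing.assert_allclose(loaded.predict_params(ages)[p], v, rtol=1e-12)
    assert predict_params(loaded, 13.0) == res.predict_dist_params(13.0)
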