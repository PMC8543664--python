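"""Study orchestration: conditions, estimation specs, reduced runs."""

import numpy as np
import pytest

from normtrade import (
    Condition,
    StudyConfig,
    all_populations,
    build_estimation_spec,
    build_population,
    enumerate_conditions,
    run_study,
)
from normtrade.study import applicable_models, replicate_seed


def test_applicable_models_per_population(ids_pop, lin_pop):
    full = applicable_models(ids_pop)  # NL-HeNN: fully flexible
    assert set(full) == {
        "True[linear/splines]",
        "True[poly]",
        "BCPE",
        "Strict[long]",
        "Strict[trans]",
        "Strict[long,trans]",
    }
    restricted = applicable_models(lin_pop)  # Li-HoNo: most restricted
    assert set(restricted) == {
        "True[linear/splines]",
        "BCPE",
        "Flex[long]",
        "Flex[trans]",
        "Flex[long,trans]",
    }


def test_combination_and_condition_counts():
    combos = sum(len(applicable_models(p)) for p in all_populations())
    assert combos == 43
    conds = enumerate_conditions(R=1000)
    assert len(conds) == 129
    # 8 populations x 3 sample sizes x R generated samples
    samples = {(c.population.name, c.n) for c in conds}
    assert len(samples) * 1000 == 24_000


def test_condition_enumeration_is_order_stable():
    c1 = enumerate_conditions()
    c2 = enumerate_conditions()
    assert [c.label for c in c1] == [c.label for c in c2]


def test_inapplicable_condition_raises(ids_pop, lin_pop):
    with pytest.raises(ValueError):
        Condition(population=ids_pop, estimation_model="Flex[long]", n=500)
    with pytest.raises(ValueError):
        build_estimation_spec(lin_pop, "Strict[long]")
    with pytest.raises(ValueError):
        build_estimation_spec(ids_pop, "NotAModel")


def test_strict_long_trans_is_normal_linear_constant(ids_pop):
    spec = build_estimation_spec(ids_pop, "Strict[long,trans]")
    assert spec.family == "normal"
    assert spec.terms["mu"].kind == "linear"
    assert spec.terms["sigma"].kind == "intercept"


def test_bcpe_spec_carries_offset_100(ids_pop):
    spec = build_estimation_spec(ids_pop, "BCPE")
    assert spec.family == "BCPE"
    assert spec.offset == 100.0
    assert all(t.kind == "pspline" for t in spec.terms.values())


def test_true_poly_uses_population_degrees(ids_pop):
    spec = build_estimation_spec(ids_pop, "True[poly]")
    degrees = {p: t.degree for p, t in spec.terms.items()}
    assert degrees == {"mu": 4, "sigma": 2, "nu": 4, "tau": 1}
    assert all(t.kind == "poly" for t in spec.terms.values())


def test_true_model_mirrors_population_structure(lin_pop):
    spec = build_estimation_spec(lin_pop, "True[linear/splines]")
    assert spec.family == "normal"
    assert spec.terms["mu"].kind == "linear"
    assert spec.terms["sigma"].kind == "intercept"
    nl = build_population()  # nonlinear population -> P-spline mu
    spec_nl = build_estimation_spec(nl, "True[linear/splines]")
    assert spec_nl.family == "SST"
    assert spec_nl.terms["mu"].kind == "pspline"
    assert spec_nl.terms["mu"].n_knots == 6


def test_flex_trans_frees_transversal_only(lin_pop):
    spec = build_estimation_spec(lin_pop, "Flex[trans]")
    assert spec.family == "SST"
    assert spec.terms["mu"].kind == "linear"  # longitudinal part unchanged
    assert spec.terms["sigma"].kind == "pspline"
    assert spec.terms["nu"].kind == "pspline"


def test_replicate_seeds_distinct_and_bounded():
    seeds = {replicate_seed(1, p, n, r) for p in range(8) for n in range(3)
             for r in range(10)}
    assert len(seeds) == 240
    assert all(0 <= s < 2**31 for s in seeds)


@pytest.fixture(scope="module")
def tiny_study():
    cfg = StudyConfig(
        populations=[(False, False, False)],
        estimation_models=["True[linear/splines]", "Strict[long,trans]"],
        sample_sizes=(150,),
        R=3,
        I=12,
        J=8,
        seed=5,
    )
    return cfg, run_study(cfg)


def test_run_study_deterministic(tiny_study):
    cfg, res1 = tiny_study
    res2 = run_study(cfg)
    f1, f2 = res1.aggregates_frame(), res2.aggregates_frame()
    assert f1.equals(f2)


def test_run_study_accounting(tiny_study):
    _, res = tiny_study
    frame = res.aggregates_frame()
    assert len(frame) == 2
    for c in res.conditions:
        usable = len(c.grid.estimates)
        assert c.n_failed + usable == c.R  # type-1 + usable fits = R
        assert c.grid.scores.shape == (12, 8)
        assert np.all(np.abs(c.grid.stacked()) <= 5.0)


def test_run_study_writes_tables(tmp_path, tiny_study):
    cfg, res = tiny_study
    res.save(tmp_path)
    assert (tmp_path / "aggregates.csv").exists()
    assert (tmp_path / "nonconvergence.csv").exists()
    assert any((tmp_path / "cells").iterdir())
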