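"""Factorial simulation study: population x estimation model x sample size.

Enumerates the study conditions, generates one normative sample per
(population, n, replicate) — shared by every applicable estimation model,
so between-model comparisons use common random numbers — fits each
model, accumulates estimated z scores on the evaluation grid, and emits
per-condition aggregates with Monte-Carlo standard errors and
nonconvergence counts.

Estimation-model flexibility is defined relative to the population:

* ``True[linear/splines]`` mirrors the population family and the
  constancy structure of each parameter (linear mu for linear
  populations, P-splines for nonlinear ones; intercepts for constant
  parameters, P-splines for age-varying ones).
* ``True[poly]`` uses the population's own orthogonal-polynomial
  degrees (only applicable to the fully flexible population).
* ``Strict`` variants restrict the longitudinal part (linear mu) and/or
  the transversal part (normal family, constant sigma).
* ``Flex`` variants free the longitudinal part (P-spline mu on a linear
  population) and/or the transversal part (skew Student t with
  age-varying sigma, nu, tau on a homoscedastic or normal population).
* ``BCPE`` fits the Box-Cox Power Exponential with P-spline terms on
  scores + 100, back-shifting all estimated quantiles.

Applicability: the True model and BCPE always apply; a Strict variant
applies when the population actually has the structure it removes; a
Flex variant applies when the population lacks the structure it adds;
combined variants require both components.  Over the 8 populations this
yields 43 population x estimation combinations and, with 3 sample
sizes, 129 study conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bases import TermSpec
from .evaluation import EvaluationGrid, build_grid
from .model import ModelSpec, NormingModel, NormingResults
from .norming import _z_from_percentile
from .population import PopulationModel, all_populations, sample_norm_data

__all__ = [
    "ESTIMATION_MODELS",
    "Condition",
    "ConditionResult",
    "StudyConfig",
    "StudyResults",
    "applicable_models",
    "enumerate_conditions",
    "build_estimation_spec",
    "run_study",
]

ESTIMATION_MODELS = (
    "True[linear/splines]",
    "True[poly]",
    "Strict[long]",
    "Strict[trans]",
    "Strict[long,trans]",
    "Flex[long]",
    "Flex[trans]",
    "Flex[long,trans]",
    "BCPE",
)

DEFAULT_SAMPLE_SIZES = (500, 1000, 2000)
BCPE_OFFSET = 100.0


def applicable_models(pop: PopulationModel) -> list[str]:
    """Estimation models applicable to a population, in canonical order."""
    lin, homo, norm = pop.flags
    strict_long = not lin
    strict_trans = (not homo) or (not norm)
    flex_long = lin
    flex_trans = homo or norm
    rules = {
        "True[linear/splines]": True,
        "True[poly]": not lin and not homo and not norm,
        "Strict[long]": strict_long,
        "Strict[trans]": strict_trans,
        "Strict[long,trans]": strict_long and strict_trans,
        "Flex[long]": flex_long,
        "Flex[trans]": flex_trans,
        "Flex[long,trans]": flex_long and flex_trans,
        "BCPE": True,
    }
    return [m for m in ESTIMATION_MODELS if rules[m]]


@dataclass
class Condition:
    """One cell of the study design."""

    population: PopulationModel
    estimation_model: str
    n: int
    R: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.estimation_model not in applicable_models(self.population):
            raise ValueError(
                f"{self.estimation_model} is not applicable to "
                f"population {self.population.name}"
            )

    @property
    def label(self) -> str:
        return f"{self.population.name}|{self.estimation_model}|n={self.n}"


def enumerate_conditions(
    sample_sizes=DEFAULT_SAMPLE_SIZES,
    R: int = 1000,
    base: PopulationModel | None = None,
    seed: int = 0,
) -> list[Condition]:
    """All applicable (population x estimation model x n) conditions.

    43 population x estimation combinations across the 8 populations;
    129 conditions with the three study sample sizes.
    """
    out = []
    for pop in all_populations(base):
        for label in applicable_models(pop):
            for n in sample_sizes:
                out.append(
                    Condition(
                        population=pop,
                        estimation_model=label,
                        n=int(n),
                        R=R,
                        seed=seed,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# estimation-model construction
# ---------------------------------------------------------------------------

def _curve_varies(pop: PopulationModel, param: str) -> bool:
    coefs = pop.curves.get(param)
    if coefs is None:
        return False
    return any(abs(c) > 0 for c in coefs[1:])


def _mirror_term(varies: bool, knots: int) -> TermSpec:
    if varies:
        return TermSpec(kind="pspline", n_knots=knots, lam="auto")
    return TermSpec(kind="intercept")


def build_estimation_spec(
    condition_or_pop,
    estimation_model: str | None = None,
    knots: int = 6,
    gaic_penalty: float = 5.0,
    max_iterations: int = 2000,
) -> ModelSpec:
    """ModelSpec for an estimation model relative to a population."""
    if isinstance(condition_or_pop, Condition):
        pop = condition_or_pop.population
        label = condition_or_pop.estimation_model
    else:
        pop = condition_or_pop
        label = estimation_model
    if label not in ESTIMATION_MODELS:
        raise ValueError(f"unknown estimation model {label!r}")
    if label not in applicable_models(pop):
        raise ValueError(f"{label} is not applicable to population {pop.name}")

    lin, homo, norm = pop.flags
    spline = TermSpec(kind="pspline", n_knots=knots, lam="auto")

    def true_terms():
        fam = "normal" if norm else "SST"
        terms = {
            "mu": TermSpec(kind="linear") if lin else _mirror_term(True, knots),
            "sigma": _mirror_term(not homo, knots),
        }
        if fam == "SST":
            terms["nu"] = _mirror_term(_curve_varies(pop, "nu"), knots)
            terms["tau"] = _mirror_term(_curve_varies(pop, "tau"), knots)
        return fam, terms

    fam, terms = true_terms()

    if label == "True[poly]":
        fam = "SST"
        terms = {
            p: TermSpec(kind="poly", degree=len(pop.curves[p]) - 1)
            for p in ("mu", "sigma", "nu", "tau")
        }
    elif label == "Strict[long]":
        terms["mu"] = TermSpec(kind="linear")
    elif label == "Strict[trans]":
        fam = "normal"
        terms = {"mu": terms["mu"], "sigma": TermSpec(kind="intercept")}
    elif label == "Strict[long,trans]":
        fam = "normal"
        terms = {"mu": TermSpec(kind="linear"), "sigma": TermSpec(kind="intercept")}
    elif label == "Flex[long]":
        terms["mu"] = TermSpec(kind="pspline", n_knots=knots, lam="auto")
    elif label == "Flex[trans]":
        fam = "SST"
        terms = {
            "mu": terms["mu"],
            "sigma": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "nu": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "tau": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
        }
    elif label == "Flex[long,trans]":
        fam = "SST"
        terms = {
            "mu": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "sigma": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "nu": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "tau": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
        }
    elif label == "BCPE":
        fam = "BCPE"
        terms = {
            "mu": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "sigma": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "nu": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
            "tau": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
        }

    return ModelSpec(
        family=fam,
        terms=terms,
        offset=BCPE_OFFSET if label == "BCPE" else 0.0,
        max_iterations=max_iterations,
        gaic_penalty=gaic_penalty,
        label=label,
    )


# ---------------------------------------------------------------------------
# study execution
# ---------------------------------------------------------------------------

@dataclass
class ConditionResult:
    """Aggregated outcomes of one condition."""

    population: str
    estimation_model: str
    n: int
    R: int
    mean_abs_bias: float
    mean_variance: float
    mean_rmse: float
    se_abs_bias: float
    se_variance: float
    se_rmse: float
    n_failed: int          # type-1 nonconvergence: could not be estimated
    n_max_iterations: int  # type-2: hit the iteration cap (still included)
    grid: EvaluationGrid | None = None

    def as_row(self) -> dict:
        return {
            "population": self.population,
            "estimation_model": self.estimation_model,
            "n": self.n,
            "R": self.R,
            "mean_abs_bias": self.mean_abs_bias,
            "mean_variance": self.mean_variance,
            "mean_rmse": self.mean_rmse,
            "se_abs_bias": self.se_abs_bias,
            "se_variance": self.se_variance,
            "se_rmse": self.se_rmse,
            "n_failed": self.n_failed,
            "n_max_iterations": self.n_max_iterations,
        }


@dataclass
class StudyConfig:
    """Configuration of a (possibly reduced) study run."""

    populations: list | str = "all"       # flag triples or "all"
    estimation_models: list | None = None  # None = all applicable
    sample_sizes: tuple = DEFAULT_SAMPLE_SIZES
    R: int = 1000
    I: int = 1000
    J: int = 100
    seed: int = 0
    knots: int = 6
    gaic_penalty: float = 5.0
    max_iterations: int = 2000
    base: PopulationModel | None = None
    output_dir: str | None = None
    keep_grids: bool = True

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sample_sizes" in raw:
            raw["sample_sizes"] = tuple(raw["sample_sizes"])
        if "base" in raw and raw["base"] is not None:
            raw["base"] = PopulationModel.from_dict(raw["base"])
        return cls(**raw)

    def resolve_populations(self) -> list[PopulationModel]:
        if self.populations == "all":
            return all_populations(self.base)
        out = []
        for flags in self.populations:
            if isinstance(flags, str):
                lin = flags.startswith("Li")
                homo = "Ho" in flags
                norm = flags.endswith("No")
            else:
                lin, homo, norm = flags
            out.append(
                _build(self.base, lin, homo, norm)
            )
        return out


def _build(base, lin, homo, norm):
    from .population import build_population

    return build_population(base, linear_mu=lin, homoscedastic=homo, normal=norm)


def replicate_seed(master: int, pop_index: int, n_index: int, replicate: int) -> int:
    """Counter-based child seed for one generated sample (< 2**31)."""
    ss = np.random.SeedSequence([int(master), pop_index, n_index, replicate])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _zhat_grid(result: NormingResults, grid: EvaluationGrid) -> np.ndarray:
    """Clamped z estimates for every grid cell under a fitted model."""
    params = result.predict_params(grid.ages)
    fam = result.family
    work = grid.scores + result.spec.offset
    kwargs = {p: np.asarray(v)[:, None] for p, v in params.items()}
    pct = fam.cdf(work, **kwargs)
    z, _ = _z_from_percentile(pct)
    return z


@dataclass
class StudyResults:
    """Results of a study run: one ConditionResult per condition."""

    conditions: list = field(default_factory=list)
    config: StudyConfig | None = None

    def aggregates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.conditions])

    def get(self, population: str, estimation_model: str, n: int) -> ConditionResult:
        for c in self.conditions:
            if (
                c.population == population
                and c.estimation_model == estimation_model
                and c.n == n
            ):
                return c
        raise KeyError((population, estimation_model, n))

    def save(self, output_dir):
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.aggregates_frame().to_csv(out / "aggregates.csv", index=False)
        nc = self.aggregates_frame()[
            ["population", "estimation_model", "n", "n_failed", "n_max_iterations"]
        ]
        nc.to_csv(out / "nonconvergence.csv", index=False)
        cells = out / "cells"
        cells.mkdir(exist_ok=True)
        for c in self.conditions:
            if c.grid is not None and c.grid.estimates:
                stem = f"{c.population}_{c.estimation_model}_{c.n}".replace(
                    "/", "-"
                ).replace("[", "_").replace("]", "").replace(",", "-")
                c.grid.to_long_frame().to_csv(cells / f"{stem}.csv", index=False)


def _jackknife_ses(zhat: np.ndarray, z_values: np.ndarray) -> tuple[float, float, float]:
    """Delete-1 jackknife SEs of the three grid aggregates."""
    r = zhat.shape[0]
    if r < 2:
        return (np.nan, np.nan, np.nan)
    s1 = zhat.sum(axis=0)
    s2 = (zhat**2).sum(axis=0)
    z = z_values[None, None, :]
    theta = np.empty((r, 3))
    for i in range(r):
        m1 = (s1 - zhat[i]) / (r - 1)
        m2 = (s2 - zhat[i] ** 2) / (r - 1)
        bias = m1 - z[0]
        var = np.maximum(m2 - m1**2, 0.0)
        rmse = np.sqrt(np.maximum(m2 - 2 * z[0] * m1 + z[0] ** 2, 0.0))
        theta[i] = (np.abs(bias).mean(), var.mean(), rmse.mean())
    center = theta.mean(axis=0)
    se = np.sqrt((r - 1) / r * ((theta - center) ** 2).sum(axis=0))
    return tuple(float(v) for v in se)


def run_study(config: StudyConfig) -> StudyResults:
    """Run the (possibly reduced) factorial study.

    For each population x n x replicate, one normative sample is
    generated and shared by all applicable estimation models.  The run
    is deterministic given ``config.seed`` regardless of which subset of
    conditions is requested, because child seeds are counter-based.
    """
    pops = config.resolve_populations()
    results = StudyResults(config=config)
    pop_order = {p.name: i for i, p in enumerate(all_populations(config.base))}

    for pop in pops:
        pop_idx = pop_order[pop.name]
        labels = applicable_models(pop)
        if config.estimation_models is not None:
            labels = [m for m in labels if m in config.estimation_models]
        if not labels:
            continue
        specs = {
            m: build_estimation_spec(
                pop,
                m,
                knots=config.knots,
                gaic_penalty=config.gaic_penalty,
                max_iterations=config.max_iterations,
            )
            for m in labels
        }
        grid_template = build_grid(pop, I=config.I, J=config.J)
        for n_idx, n in enumerate(config.sample_sizes):
            grids = {
                m: EvaluationGrid(
                    ages=grid_template.ages,
                    z_values=grid_template.z_values,
                    scores=grid_template.scores,
                )
                for m in labels
            }
            counts = {m: {"failed": 0, "maxit": 0} for m in labels}
            for r in range(config.R):
                seed = replicate_seed(config.seed, pop_idx, n_idx, r)
                sample = sample_norm_data(pop, n, seed=seed, replicate_id=r)
                for m in labels:
                    fit_res = NormingModel(sample.ages, sample.scores, specs[m]).fit()
                    if fit_res.failed:
                        counts[m]["failed"] += 1
                        continue
                    if not fit_res.converged:
                        counts[m]["maxit"] += 1
                    grids[m].add_replicate(_zhat_grid(fit_res, grids[m]))
            for m in labels:
                grid = grids[m]
                if not grid.estimates:
                    continue
                zhat = grid.stacked()
                out = grid.outcomes()
                ses = _jackknife_ses(zhat, grid.z_values)
                results.conditions.append(
                    ConditionResult(
                        population=pop.name,
                        estimation_model=m,
                        n=int(n),
                        R=config.R,
                        mean_abs_bias=float(np.abs(out["bias"]).mean()),
                        mean_variance=float(out["variance"].mean()),
                        mean_rmse=float(out["rmse"].mean()),
                        se_abs_bias=ses[0],
                        se_variance=ses[1],
                        se_rmse=ses[2],
                        n_failed=counts[m]["failed"],
                        n_max_iterations=counts[m]["maxit"],
                        grid=grid if config.keep_grids else None,
                    )
                )
    if config.output_dir:
        results.save(config.output_dir)
    return results
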