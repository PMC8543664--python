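"""Synthetic population models and normative-sample generation.

The data-generating truth is a conditional score distribution over ages
5-21 whose four parameters follow polynomials of age on the link scale:
degree 4 for mu and ln(nu), degree 2 for ln(sigma), degree 1 for
ln(tau - 2) — the structure selected for the intelligence-test subtest
that anchors the study.  Toggling three restrictions (linearity of mu,
homoscedasticity, normality) over the full flexible model yields the
2^3 = 8 factorial population models.

The exact coefficients of the anchoring empirical model were never
published; the default configuration here is an explicit, documented
"IDS-like" choice reproducing its qualitative shape (mean rising steeply
in childhood then decelerating; mildly age-varying spread; left skew;
moderate heavy tails) and is fully user-overridable.  Polynomials are
expressed in the scaled age u = (age - 13) / 8, so u spans [-1, 1] over
the age range.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import special

from .families import DistParams, get_family

__all__ = [
    "PopulationModel",
    "NormativeSample",
    "DEFAULT_IDS_CURVES",
    "default_ids_population",
    "build_population",
    "all_populations",
    "population_params",
    "sample_norm_data",
    "population_score_at_z",
]

AGE_RANGE = (5.0, 21.0)

# link-scale polynomial coefficients in u = (age - 13) / 8, low order first
DEFAULT_IDS_CURVES: dict[str, list[float]] = {
    "mu": [22.0, 11.0, -4.5, 0.5, 1.0],          # identity link
    "sigma": [1.70, -0.05, -0.15],               # log link
    "nu": [-0.25, 0.15, -0.10, 0.05, 0.05],      # log link
    "tau": [1.5, -0.3],                          # log(tau - 2) link
}

_LINK_INVERT = {
    "mu": lambda eta: eta,
    "sigma": np.exp,
    "nu": np.exp,
    "tau": lambda eta: 2.0 + np.exp(eta),
}


def _scale_age(age):
    lo, hi = AGE_RANGE
    return (np.asarray(age, dtype=float) - (lo + hi) / 2.0) / ((hi - lo) / 2.0)


@dataclass
class PopulationModel:
    """A data-generating truth: family + per-parameter age curves.

    ``curves`` maps parameter name to polynomial coefficients (low order
    first) in the scaled age, on that parameter's link scale.  The three
    flags record which restrictions were applied relative to the fully
    flexible model.
    """

    family: str = "SST"
    curves: dict = field(default_factory=lambda: dict(DEFAULT_IDS_CURVES))
    age_range: tuple = AGE_RANGE
    linear_mu: bool = False
    homoscedastic: bool = False
    normal: bool = False

    def __post_init__(self):
        if self.normal and self.family != "normal":
            raise ValueError("normal-flagged populations must use the normal family")

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.linear_mu, self.homoscedastic, self.normal)

    @property
    def name(self) -> str:
        return (
            ("Li" if self.linear_mu else "NL")
            + "-"
            + ("Ho" if self.homoscedastic else "He")
            + ("No" if self.normal else "NN")
        )

    def _check_age(self, age):
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_range
        if np.any((age < lo - 1e-9) | (age > hi + 1e-9)):
            raise ValueError(f"age outside the population range [{lo}, {hi}]")
        return age

    def params_at(self, age) -> dict:
        """Distributional parameters (natural scale) at the given age(s)."""
        age = self._check_age(age)
        u = _scale_age(age)
        out = {}
        for p, coefs in self.curves.items():
            out[p] = _LINK_INVERT[p](npoly.polyval(u, np.asarray(coefs, dtype=float)))
        return out

    def dist_params(self, age: float) -> DistParams:
        d = self.params_at(age)
        return DistParams(
            mu=float(d["mu"]),
            sigma=float(d["sigma"]),
            nu=float(d.get("nu", 1.0)),
            tau=float(d.get("tau", 10.0)),
        )

    def cdf(self, age, score) -> np.ndarray:
        params = self.params_at(age)
        return get_family(self.family).cdf(np.asarray(score, dtype=float), **params)

    def score_at_z(self, age, z) -> np.ndarray:
        """Score whose conditional cdf at ``age`` equals Phi(z)."""
        params = self.params_at(age)
        q = special.ndtr(np.asarray(z, dtype=float))
        return get_family(self.family).ppf(q, **params)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "curves": {p: list(map(float, c)) for p, c in self.curves.items()},
            "age_range": list(self.age_range),
            "linear_mu": self.linear_mu,
            "homoscedastic": self.homoscedastic,
            "normal": self.normal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        d = dict(d)
        d["age_range"] = tuple(d.get("age_range", AGE_RANGE))
        return cls(**d)


@dataclass
class NormativeSample:
    """One generated normative sample: evenly spaced ages, random scores."""

    ages: np.ndarray
    scores: np.ndarray
    population_id: str = ""
    replicate_id: int = 0
    seed: int | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.ages.shape != self.scores.shape:
            raise ValueError("ages and scores must have equal length")

    def __len__(self):
        return self.ages.size

    def as_tuple(self):
        return self.ages, self.scores

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages, "score": self.scores})

    def to_csv(self, path_or_buf):
        header = (
            f"# population_id={self.population_id} "
            f"replicate_id={self.replicate_id} seed={self.seed}\n"
        )
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            self.to_dataframe().to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header)
                self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "NormativeSample":
        import pandas as pd

        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                buf = io.StringIO(fh.read())
            else:
                buf = io.StringIO(first + fh.read())
        df = pd.read_csv(buf)
        seed = meta.get("seed")
        return cls(
            ages=df["age"].to_numpy(),
            scores=df["score"].to_numpy(),
            population_id=meta.get("population_id", ""),
            replicate_id=int(meta.get("replicate_id", 0) or 0),
            seed=None if seed in (None, "None") else int(seed),
        )


# ---------------------------------------------------------------------------
# construction of the factorial populations
# ---------------------------------------------------------------------------

def _linearize_mu(coefs, n_grid: int = 401) -> list[float]:
    """Least-squares line through the flexible mu curve over the age range."""
    u = np.linspace(-1.0, 1.0, n_grid)
    y = npoly.polyval(u, np.asarray(coefs, dtype=float))
    return [float(c) for c in npoly.polyfit(u, y, 1)]


def _constant_sigma(coefs, n_grid: int = 401) -> list[float]:
    """Age-average of the flexible sigma curve, as a constant on the log scale."""
    u = np.linspace(-1.0, 1.0, n_grid)
    sigma = np.exp(npoly.polyval(u, np.asarray(coefs, dtype=float)))
    return [float(np.log(sigma.mean()))]


def build_population(
    base: PopulationModel | dict | None = None,
    linear_mu: bool = False,
    homoscedastic: bool = False,
    normal: bool = False,
) -> PopulationModel:
    """Apply restriction flags to the fully flexible population model.

    ``linear_mu`` replaces the mu curve by its least-squares line,
    ``homoscedastic`` replaces the sigma curve by its age-average, and
    ``normal`` switches to the exact Gaussian family (the nu = 1,
    tau = infinity limit of the skew Student t).
    """
    if base is None:
        base = PopulationModel()
    elif isinstance(base, dict):
        base = PopulationModel.from_dict(base)
    curves = {p: list(c) for p, c in base.curves.items()}
    if linear_mu:
        curves["mu"] = _linearize_mu(curves["mu"])
    if homoscedastic:
        curves["sigma"] = _constant_sigma(curves["sigma"])
    family = base.family
    if normal:
        family = "normal"
        curves.pop("nu", None)
        curves.pop("tau", None)
    return PopulationModel(
        family=family,
        curves=curves,
        age_range=base.age_range,
        linear_mu=linear_mu,
        homoscedastic=homoscedastic,
        normal=normal,
    )


def default_ids_population() -> PopulationModel:
    """The fully flexible IDS-like population (NL-HeNN)."""
    return PopulationModel()


def all_populations(base: PopulationModel | None = None) -> list[PopulationModel]:
    """The 8 factorial populations, ordered most flexible first."""
    out = []
    for lin in (False, True):
        for homo in (False, True):
            for norm in (False, True):
                out.append(
                    build_population(
                        base, linear_mu=lin, homoscedastic=homo, normal=norm
                    )
                )
    return out


# ---------------------------------------------------------------------------
# op surface
# ---------------------------------------------------------------------------

def population_params(pop: PopulationModel, age: float) -> DistParams:
    """Distributional parameters of the population at one age."""
    return pop.dist_params(age)


def sample_norm_data(pop: PopulationModel, n: int, seed=None,
                     replicate_id: int = 0) -> NormativeSample:
    """Generate a normative sample of size ``n`` from the population.

    Ages are the ``n`` evenly spaced values on the age range (inclusive);
    each score is an independent draw from the conditional distribution
    at its age, by inverse-cdf sampling.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    lo, hi = pop.age_range
    ages = np.linspace(lo, hi, int(n))
    params = pop.params_at(ages)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    scores = get_family(pop.family).ppf(u, **params)
    return NormativeSample(
        ages=ages,
        scores=scores,
        population_id=pop.name,
        replicate_id=replicate_id,
        seed=seed if isinstance(seed, int) else None,
    )


def population_score_at_z(pop: PopulationModel, age, z):
    """Score at conditional population z (cdf(score | age) = Phi(z))."""
    return pop.score_at_z(age, z)
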