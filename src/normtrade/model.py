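"""Penalized distributional-regression fitting (GAMLSS-style).

A :class:`NormingModel` couples a normative sample (ages, scores) with a
:class:`ModelSpec` describing, for each distributional parameter (mu,
sigma, nu, tau), a link function and an age term (intercept, linear,
orthogonal polynomial, or P-spline).  :meth:`NormingModel.fit` maximizes
the penalized likelihood by backfitting across the parameters: each
parameter's coefficients are updated by one penalized Newton step on the
link-scale predictor (score and curvature obtained by numerical
differentiation of the exact log-likelihood), holding the other
parameters fixed, cycling until the global deviance stabilizes.

Smoothing parameters of P-spline terms flagged ``lam="auto"`` are chosen
inside each backfitting update by golden-section search on the local
GAIC of the working penalized regression (weighted RSS + k * edf), with
penalty ``k`` taken from ``ModelSpec.gaic_penalty`` (5 in the study
design; ``ln n`` gives BIC-type selection).

The module also provides the model-selection utilities used by the
norming workflow: ``gaic``, ``select_lambda`` (explicit outer search),
``select_model_bic`` and the 648-candidate polynomial grid enumerator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bases import TermSpec, TermBasis, build_term
from .families import DistParams, Family, get_family, LINKS

__all__ = [
    "ModelSpec",
    "NormingModel",
    "NormingResults",
    "fit",
    "gaic",
    "select_lambda",
    "select_model_bic",
    "enumerate_polynomial_grid",
    "predict_params",
]

PARAM_ORDER = ("mu", "sigma", "nu", "tau")

# link-scale clip bounds keep inverted parameters family-valid and finite
_ETA_BOUNDS = {
    ("SST", "sigma"): (-20.0, 20.0),
    ("SST", "nu"): (-7.0, 7.0),
    ("SST", "tau"): (-12.0, 12.0),
    ("BCPE", "sigma"): (-20.0, 20.0),
    ("BCPE", "nu"): (-8.0, 8.0),
    ("BCPE", "tau"): (-3.0, 6.0),
    ("normal", "sigma"): (-20.0, 20.0),
}

_NUMDIFF_H = 1e-5


@dataclass
class ModelSpec:
    """Term structure, links and fitting controls of an estimation model."""

    family: str = "SST"
    terms: dict = field(default_factory=dict)
    links: dict | None = None
    offset: float = 0.0
    max_iterations: int = 2000
    tolerance: float = 1e-3
    gaic_penalty: float = 5.0
    label: str | None = None

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        fam = get_family(self.family)
        terms = dict(self.terms)
        for p in fam.param_names:
            t = terms.get(p, TermSpec(kind="intercept"))
            if isinstance(t, dict):
                t = TermSpec.from_dict(t)
            terms[p] = t
        self.terms = {p: terms[p] for p in fam.param_names}

    def resolved_links(self) -> dict:
        fam = get_family(self.family)
        links = dict(zip(fam.param_names, fam.default_links))
        if self.links:
            links.update(self.links)
        return links

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "terms": {p: t.to_dict() for p, t in self.terms.items()},
            "links": self.resolved_links(),
            "offset": self.offset,
            "max_iterations": self.max_iterations,
            "tolerance": self.tolerance,
            "gaic_penalty": self.gaic_penalty,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["terms"] = {p: TermSpec.from_dict(t) for p, t in d.get("terms", {}).items()}
        return cls(**d)


class NormingModel:
    """A distributional norming model bound to a normative sample.

    Parameters
    ----------
    ages, scores : array-like
        The normative sample. ``spec.offset`` is added to the scores
        before fitting (the BCPE workflow fits scores + 100); all
        downstream cdf/quantile computations transparently back-shift.
    spec : ModelSpec
    """

    def __init__(self, ages, scores, spec: ModelSpec):
        ages = np.asarray(ages, dtype=float)
        scores = np.asarray(scores, dtype=float)
        if ages.size == 0 or ages.shape != scores.shape:
            raise ValueError("ages and scores must be equal-length nonempty vectors")
        if not (np.all(np.isfinite(ages)) and np.all(np.isfinite(scores))):
            raise ValueError("ages and scores must be finite")
        self.ages = ages
        self.scores = scores
        self.spec = spec
        self.family: Family = get_family(spec.family)
        self.links = spec.resolved_links()
        self.work_scores = scores + spec.offset
        if self.family.name == "BCPE" and np.any(self.work_scores <= 0):
            raise ValueError(
                "BCPE requires positive scores after the offset; "
                "increase ModelSpec.offset"
            )
        self.bases: dict[str, TermBasis] = {
            p: build_term(ages, spec.terms[p]) for p in self.family.param_names
        }
        self.nobs = ages.size

    @classmethod
    def from_dataframe(cls, data, spec: ModelSpec, age_col="age", score_col="score"):
        return cls(np.asarray(data[age_col]), np.asarray(data[score_col]), spec)

    # ------------------------------------------------------------------
    # likelihood machinery
    # ------------------------------------------------------------------

    def _clip_eta(self, p: str, eta: np.ndarray) -> np.ndarray:
        bounds = _ETA_BOUNDS.get((self.family.name, p))
        if bounds is None:
            return eta
        return np.clip(eta, *bounds)

    def _params_from_etas(self, etas: dict) -> dict:
        out = {}
        for p in self.family.param_names:
            out[p] = LINKS[self.links[p]].invert(self._clip_eta(p, etas[p]))
        return out

    def _ll_obs(self, etas: dict) -> np.ndarray:
        params = self._params_from_etas(etas)
        return self.family.logpdf(self.work_scores, **params)

    def _penalty_value(self, betas: dict, lams: dict) -> float:
        tot = 0.0
        for p, basis in self.bases.items():
            if basis.penalized and lams.get(p, 0.0) > 0:
                b = betas[p]
                tot += lams[p] * float(b @ basis.penalty @ b)
        return tot

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------

    def _initial_betas(self) -> dict:
        fam = self.family
        betas = {}
        x_mu = self.bases["mu"].matrix
        y = self.work_scores
        ridge = 1e-8 * np.eye(x_mu.shape[1])
        pen_mu = self.bases["mu"].penalty
        a = x_mu.T @ x_mu + ridge
        if pen_mu is not None:
            a = a + 1.0 * pen_mu
        betas["mu"] = np.linalg.solve(a, x_mu.T @ y)
        resid = y - x_mu @ betas["mu"]
        sd = max(float(np.std(resid)), 1e-6)
        for p in fam.param_names[1:]:
            basis = self.bases[p]
            if p == "sigma":
                target = LINKS[self.links[p]].apply(sd)
            elif p == "tau":
                target = float(
                    LINKS[self.links[p]].apply(
                        getattr(fam.init_params, "tau", 10.0)
                    )
                )
            else:
                target = float(
                    LINKS[self.links[p]].apply(getattr(fam.init_params, "nu", 1.0))
                )
            x = basis.matrix
            a = x.T @ x + 1e-8 * np.eye(x.shape[1])
            if basis.penalized:
                a = a + 1.0 * basis.penalty
            betas[p] = np.linalg.solve(a, x.T @ np.full(self.nobs, target))
        return betas

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------

    def fit(self) -> "NormingResults":
        """Penalized maximum likelihood by backfitting across parameters.

        Never raises on numerical failure: a failed fit is returned with
        ``failed=True`` and no coefficients (type-1 nonconvergence).
        """
        try:
            return self._fit_inner()
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            return NormingResults._failed(self, str(exc))

    def _fit_inner(self) -> "NormingResults":
        spec = self.spec
        betas = self._initial_betas()
        etas = {p: self.bases[p].matrix @ betas[p] for p in self.family.param_names}
        lams = {
            p: (0.0 if not self.bases[p].penalized
                else (float(self.bases[p].spec.lam)
                      if self.bases[p].spec.lam != "auto" else 10.0))
            for p in self.family.param_names
        }
        auto = {
            p: self.bases[p].penalized and self.bases[p].spec.lam == "auto"
            for p in self.family.param_names
        }

        ll = self._ll_obs(etas)
        if not np.all(np.isfinite(ll)):
            raise ValueError("non-finite log-likelihood at initialization")
        init_betas = {p: b.copy() for p, b in betas.items()}
        gdev = -2.0 * float(ll.sum())
        pdev = gdev + self._penalty_value(betas, lams)

        n_iter = 0
        converged = False
        frozen = False
        polish_left = 1

        while n_iter < spec.max_iterations:
            n_iter += 1
            for p in self.family.param_names:
                pdev, ll = self._update_one(
                    p, betas, etas, lams, auto[p] and not frozen, pdev, ll
                )
            gdev_new = -2.0 * float(ll.sum())
            pdev = gdev_new + self._penalty_value(betas, lams)
            change = abs(gdev_new - gdev)
            gdev = gdev_new
            if change < spec.tolerance:
                if polish_left > 0:
                    # one extra cycle with smoothing frozen sharpens the
                    # optimum (Newton is quadratic near convergence)
                    polish_left -= 1
                    frozen = True
                    continue
                converged = True
                break

        # the penalized likelihood (at the final smoothing parameters)
        # must not be worse than at initialization
        init_pdev = -2.0 * float(
            self._ll_obs(
                {p: self.bases[p].matrix @ init_betas[p]
                 for p in self.family.param_names}
            ).sum()
        ) + self._penalty_value(init_betas, lams)
        if pdev > init_pdev + 1e-6:
            raise ValueError("penalized deviance increased during fitting")
        ll = self._ll_obs(etas)
        llf = float(ll.sum())
        edf = self._edf(betas, etas, lams)
        return NormingResults(
            model=self,
            spec=spec,
            params=betas,
            lambdas=lams,
            edf=edf,
            llf=llf,
            deviance=-2.0 * llf,
            iterations=n_iter,
            converged=converged,
            failed=False,
        )

    def _score_weights(self, p: str, etas: dict, ll0: np.ndarray):
        h = _NUMDIFF_H
        up = dict(etas)
        up[p] = etas[p] + h
        llp = self._ll_obs(up)
        up[p] = etas[p] - h
        llm = self._ll_obs(up)
        u = (llp - llm) / (2.0 * h)
        w = -(llp - 2.0 * ll0 + llm) / (h * h)
        bad = ~np.isfinite(w) | (w <= 1e-10)
        if bad.any():
            pos = w[~bad]
            fallback = float(np.median(pos)) if pos.size else 1e-2
            w = np.where(bad, np.maximum(u * u, fallback), w)
        u = np.where(np.isfinite(u), u, 0.0)
        return u, np.clip(w, 1e-10, 1e8)

    def _update_one(self, p, betas, etas, lams, select_lam, pdev, ll):
        basis = self.bases[p]
        x = basis.matrix
        u, w = self._score_weights(p, etas, ll)
        z = etas[p] + u / w
        xtw = x.T * w
        a0 = xtw @ x
        b_vec = xtw @ z

        if basis.penalized and select_lam:
            lams[p] = _golden_gaic(
                a0, b_vec, basis.penalty, x, w, z, self.spec.gaic_penalty
            )
        pen = lams[p] * basis.penalty if basis.penalized else 0.0
        beta_new = _solve_stable(a0 + pen, b_vec)

        # step control: accept the Newton step, halving toward the old
        # coefficients while it worsens the penalized deviance
        beta_old = betas[p]
        step = 1.0
        for _ in range(6):
            cand = beta_old + step * (beta_new - beta_old)
            etas_cand = dict(etas)
            etas_cand[p] = x @ cand
            ll_cand = self._ll_obs(etas_cand)
            if np.all(np.isfinite(ll_cand)):
                betas_try = dict(betas)
                betas_try[p] = cand
                pdev_cand = -2.0 * float(ll_cand.sum()) + self._penalty_value(
                    betas_try, lams
                )
                if pdev_cand <= pdev + 1e-9:
                    betas[p] = cand
                    etas[p] = etas_cand[p]
                    return pdev_cand, ll_cand
            step *= 0.5
        return pdev, ll  # keep the old coefficients for this cycle

    def _edf(self, betas, etas, lams) -> dict:
        ll0 = self._ll_obs(etas)
        edf = {}
        for p in self.family.param_names:
            basis = self.bases[p]
            if not basis.penalized or lams[p] <= 0:
                edf[p] = float(basis.n_coef)
                continue
            _, w = self._score_weights(p, etas, ll0)
            x = basis.matrix
            a0 = (x.T * w) @ x
            a = a0 + lams[p] * basis.penalty + 1e-9 * np.eye(a0.shape[0])
            edf[p] = float(np.trace(np.linalg.solve(a, a0)))
        edf["total"] = float(sum(v for k, v in edf.items() if k != "total"))
        return edf


def _solve_stable(a, b):
    """Solve a (near-)PD system, escalating a ridge only when necessary."""
    try:
        out = np.linalg.solve(a, b)
        if np.all(np.isfinite(out)):
            return out
    except np.linalg.LinAlgError:
        pass
    scale = np.trace(a) / a.shape[0] + 1.0
    for eps in (1e-12, 1e-9, 1e-6, 1e-3):
        try:
            out = np.linalg.solve(a + eps * scale * np.eye(a.shape[0]), b)
            if np.all(np.isfinite(out)):
                return out
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("singular working system")


def _golden_gaic(a0, b_vec, pen, x, w, z, k) -> float:
    """Golden-section on log10(lambda) of the working-model GAIC.

    The search interval is scaled by tr(X'WX)/tr(P) so that smoothing
    selection is invariant to the magnitude of the working weights.
    """
    scale = max(np.trace(a0) / max(np.trace(pen), 1e-12), 1e-12)

    def crit(log_lam):
        lam = 10.0 ** log_lam * scale
        a = a0 + lam * pen
        try:
            beta = np.linalg.solve(a, b_vec)
        except np.linalg.LinAlgError:
            return np.inf, lam
        resid = z - x @ beta
        rss = float(w @ (resid * resid))
        edf = float(np.trace(np.linalg.solve(a, a0)))
        return rss + k * edf, lam

    lo, hi = -6.0, 8.0
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - phi * (hi - lo)
    d = lo + phi * (hi - lo)
    fc, _ = crit(c)
    fd, _ = crit(d)
    for _ in range(30):
        if fc <= fd:
            hi, d, fd = d, c, fc
            c = hi - phi * (hi - lo)
            fc, _ = crit(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + phi * (hi - lo)
            fd, _ = crit(d)
    best = c if fc <= fd else d
    # prefer the smoother end on a flat criterion
    f_best = min(fc, fd)
    f_hi, _ = crit(8.0)
    if f_hi <= f_best + 1e-9:
        best = 8.0
    return 10.0 ** best * scale


@dataclass
class NormingResults:
    """Fitted norming model: coefficients, edf, likelihood, convergence.

    Self-contained for prediction: carries the link set, score offset and
    realized bases, so conditional distribution parameters — and hence
    percentiles, normalized z scores and centile curves — can be computed
    at any age without the training sample.
    """

    model: NormingModel | None
    spec: ModelSpec
    params: dict | None
    lambdas: dict
    edf: dict
    llf: float
    deviance: float
    iterations: int
    converged: bool
    failed: bool
    message: str = ""

    @classmethod
    def _failed(cls, model, message: str) -> "NormingResults":
        return cls(
            model=model,
            spec=model.spec,
            params=None,
            lambdas={},
            edf={},
            llf=np.nan,
            deviance=np.nan,
            iterations=0,
            converged=False,
            failed=True,
            message=message,
        )

    # ------------------------------------------------------------------

    def _check_usable(self):
        if self.failed or self.params is None:
            raise ValueError(f"fit failed ({self.message or 'no coefficients'})")

    @property
    def family(self) -> Family:
        return get_family(self.spec.family)

    @property
    def nobs(self) -> int:
        return self.model.nobs if self.model is not None else self._nobs

    @property
    def edf_total(self) -> float:
        return self.edf.get("total", np.nan)

    def predict_params(self, ages) -> dict:
        """Distributional parameters (natural scale) at the given ages."""
        self._check_usable()
        ages_arr = np.atleast_1d(np.asarray(ages, dtype=float))
        if not np.all(np.isfinite(ages_arr)):
            raise ValueError("ages must be finite")
        fam = self.family
        links = self.spec.resolved_links()
        bases = self.model.bases if self.model is not None else self._bases
        out = {}
        for p in fam.param_names:
            eta = bases[p].evaluate(ages_arr) @ self.params[p]
            bounds = _ETA_BOUNDS.get((fam.name, p))
            if bounds is not None:
                eta = np.clip(eta, *bounds)
            out[p] = LINKS[links[p]].invert(eta)
        return out

    def predict_dist_params(self, age: float) -> DistParams:
        d = self.predict_params([age])
        vals = {k: float(v[0]) for k, v in d.items()}
        return DistParams(
            mu=vals["mu"],
            sigma=vals["sigma"],
            nu=vals.get("nu", 1.0),
            tau=vals.get("tau", 10.0),
        )

    def cdf(self, ages, scores) -> np.ndarray:
        """Estimated conditional cdf of raw scores at the given ages."""
        self._check_usable()
        ages = np.asarray(ages, dtype=float)
        scores = np.asarray(scores, dtype=float)
        params = self.predict_params(ages.ravel())
        work = scores.ravel() + self.spec.offset
        p = self.family.cdf(work, **params)
        return p.reshape(scores.shape)

    def ppf(self, ages, q) -> np.ndarray:
        """Estimated conditional score quantiles (offset back-shifted)."""
        self._check_usable()
        ages = np.asarray(ages, dtype=float)
        q = np.broadcast_to(np.asarray(q, dtype=float), ages.shape).ravel()
        params = self.predict_params(ages.ravel())
        s = self.family.ppf(q, **params)
        return (s - self.spec.offset).reshape(ages.shape)

    def gaic(self, k: float) -> float:
        self._check_usable()
        return -2.0 * self.llf + k * self.edf_total

    @property
    def aic(self) -> float:
        return self.gaic(2.0)

    @property
    def bic(self) -> float:
        return self.gaic(np.log(self.nobs))

    # convenience delegations -------------------------------------------------

    def estimate_z(self, age, score):
        from .norming import estimate_z as _ez

        return _ez(self, age, score)

    def centile_curves(self, ages, percentiles):
        from .norming import centile_curves as _cc

        return _cc(self, ages, percentiles)

    def quantile_residuals(self, ages=None, scores=None):
        from .diagnostics import quantile_residuals as _qr

        if ages is None:
            ages, scores = self.model.ages, self.model.scores
        return _qr(self, (ages, scores))

    def summary(self) -> str:
        lines = [
            f"Norming model: family={self.spec.family}"
            + (f"  [{self.spec.label}]" if self.spec.label else ""),
            f"  observations: {self.nobs}",
            f"  log-likelihood: {self.llf:.4f}   global deviance: {self.deviance:.4f}",
            f"  AIC: {self.aic:.2f}   BIC: {self.bic:.2f}",
            f"  iterations: {self.iterations}   converged: {self.converged}",
            f"  {'param':<7}{'term':<12}{'edf':>8}{'lambda':>12}",
        ]
        for p in self.family.param_names:
            t = self.spec.terms[p]
            lam = self.lambdas.get(p, 0.0)
            lam_s = f"{lam:.4g}" if (t.kind == "pspline") else "-"
            lines.append(f"  {p:<7}{t.kind:<12}{self.edf.get(p, 0):>8.2f}{lam_s:>12}")
        lines.append(f"  total edf: {self.edf_total:.2f}")
        return "\n".join(lines)

    # serialization -----------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_usable()
        bases = self.model.bases if self.model is not None else self._bases
        return {
            "spec": self.spec.to_dict(),
            "bases": {p: b.state_dict() for p, b in bases.items()},
            "coefficients": {p: v.tolist() for p, v in self.params.items()},
            "lambdas": self.lambdas,
            "edf": self.edf,
            "llf": self.llf,
            "deviance": self.deviance,
            "iterations": self.iterations,
            "converged": self.converged,
            "nobs": self.nobs,
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NormingResults":
        spec = ModelSpec.from_dict(d["spec"])
        res = cls(
            model=None,
            spec=spec,
            params={p: np.asarray(v, dtype=float) for p, v in d["coefficients"].items()},
            lambdas=d.get("lambdas", {}),
            edf=d.get("edf", {}),
            llf=d["llf"],
            deviance=d["deviance"],
            iterations=d.get("iterations", 0),
            converged=d.get("converged", True),
            failed=False,
        )
        res._bases = {p: TermBasis.from_state(s) for p, s in d["bases"].items()}
        res._nobs = d.get("nobs", 0)
        return res

    @classmethod
    def load(cls, path) -> "NormingResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def _as_xy(sample):
    if isinstance(sample, tuple):
        return np.asarray(sample[0], dtype=float), np.asarray(sample[1], dtype=float)
    return np.asarray(sample["age"], dtype=float), np.asarray(sample["score"], dtype=float)


def fit(sample, spec: ModelSpec) -> NormingResults:
    """Fit ``spec`` to a sample given as ``(ages, scores)`` or a DataFrame."""
    ages, scores = _as_xy(sample)
    return NormingModel(ages, scores, spec).fit()


def gaic(result: NormingResults, k: float) -> float:
    """Generalized Akaike information criterion: -2 loglik + k * edf."""
    return result.gaic(k)


def select_lambda(sample, spec: ModelSpec, k: float = 5.0) -> ModelSpec:
    """Fix the smoothing parameters of all ``lam="auto"`` P-spline terms.

    Performs an explicit outer search: each auto term in turn is profiled
    over a log-spaced lambda grid (with golden-section refinement around
    the grid optimum), refitting the full model and scoring by global
    GAIC(k).  Returns a copy of ``spec`` with the selected lambdas fixed.
    """
    ages, scores = _as_xy(sample)
    auto_params = [
        p for p, t in spec.terms.items() if t.kind == "pspline" and t.lam == "auto"
    ]
    if not auto_params:
        return spec

    terms = {p: TermSpec.from_dict(t.to_dict()) for p, t in spec.terms.items()}

    def fit_at(current_terms):
        s = ModelSpec(
            family=spec.family,
            terms=current_terms,
            links=spec.links,
            offset=spec.offset,
            max_iterations=spec.max_iterations,
            tolerance=spec.tolerance,
            gaic_penalty=k,
            label=spec.label,
        )
        return NormingModel(ages, scores, s).fit()

    grid = np.logspace(-4, 6, 11)
    for p in auto_params:
        best_lam, best_crit = None, np.inf
        for lam in grid:
            terms[p].lam = float(lam)
            res = fit_at(terms)
            if res.failed:
                continue
            crit = res.gaic(k)
            if crit < best_crit - 1e-9:
                best_crit, best_lam = crit, float(lam)
        if best_lam is None:
            raise ValueError(f"all candidate fits failed while profiling {p}")
        terms[p].lam = best_lam

    out = ModelSpec(
        family=spec.family,
        terms=terms,
        links=spec.links,
        offset=spec.offset,
        max_iterations=spec.max_iterations,
        tolerance=spec.tolerance,
        gaic_penalty=spec.gaic_penalty,
        label=spec.label,
    )
    return out


def select_model_bic(sample, candidates: Sequence[ModelSpec]):
    """Fit every candidate and return ``(spec, results)`` with minimal BIC.

    Failed fits are skipped; ties are broken toward fewer effective df,
    then toward the earlier candidate.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    ages, scores = _as_xy(sample)
    best = None
    for idx, cand in enumerate(candidates):
        res = NormingModel(ages, scores, cand).fit()
        if res.failed:
            continue
        key = (res.bic, res.edf_total, idx)
        if best is None or key < best[0]:
            best = (key, cand, res)
    if best is None:
        raise ValueError("all candidate fits failed")
    return best[1], best[2]


def enumerate_polynomial_grid(
    family: str = "SST",
    mu_degrees=range(6),
    sigma_degrees=range(6),
    nu_degrees=range(6),
    tau_degrees=range(3),
) -> list[ModelSpec]:
    """The candidate grid of orthogonal-polynomial models (648 for SST).

    All combinations of polynomial degrees 0..5 for mu, sigma, nu and
    0..2 for tau, as used to select the data-generating model structure.
    """
    out = []
    for dm in mu_degrees:
        for ds in sigma_degrees:
            for dn in nu_degrees:
                for dt in tau_degrees:
                    out.append(
                        ModelSpec(
                            family=family,
                            terms={
                                "mu": TermSpec(kind="poly", degree=dm),
                                "sigma": TermSpec(kind="poly", degree=ds),
                                "nu": TermSpec(kind="poly", degree=dn),
                                "tau": TermSpec(kind="poly", degree=dt),
                            },
                            label=f"poly({dm},{ds},{dn},{dt})",
                        )
                    )
    return out


def predict_params(result: NormingResults, age) -> DistParams:
    """Conditional distribution parameters at one age, as DistParams."""
    return result.predict_dist_params(float(age))
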