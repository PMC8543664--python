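"""Visual-diagnostic data products: quantile residuals and worm plots.

Normalized quantile residuals are Phi^{-1} of each observation's fitted
conditional cdf; under a correctly specified model they are standard
normal.  A worm plot is a detrended Q-Q plot of these residuals,
optionally conditional on age bins: deviations near zero indicate good
fit, systematic shapes indicate misfit (underfitting), and comparison
with a deliberately over-smooth / over-flexible pair of fits separates
under- from overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .bases import TermSpec
from .model import ModelSpec, NormingModel, NormingResults

__all__ = ["WormPlotData", "quantile_residuals", "worm_plot_data", "fit_three_way",
           "worm_plot"]

_P_EPS = 1e-15


def _as_sample(sample):
    if hasattr(sample, "as_tuple"):
        return sample.as_tuple()
    if isinstance(sample, tuple):
        return np.asarray(sample[0], float), np.asarray(sample[1], float)
    return np.asarray(sample["age"], float), np.asarray(sample["score"], float)


def quantile_residuals(fit, sample) -> np.ndarray:
    """Normalized quantile residuals of a sample under a fitted model.

    ``fit`` may be a :class:`~normtrade.model.NormingResults` or any
    object exposing ``cdf(ages, scores)`` — in particular a
    :class:`~normtrade.population.PopulationModel`, which gives the
    residuals under the data-generating truth.
    """
    ages, scores = _as_sample(sample)
    p = np.asarray(fit.cdf(ages, scores), dtype=float)
    return special.ndtri(np.clip(p, _P_EPS, 1.0 - _P_EPS))


@dataclass
class WormPlotData:
    """Detrended Q-Q data per age bin."""

    bins: list = field(default_factory=list)

    def max_abs_deviation(self) -> float:
        devs = [np.max(np.abs(b["deviation"])) for b in self.bins if b["n"] > 0]
        return float(max(devs)) if devs else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.bins):
            for t, r, d in zip(b["theoretical"], b["ordered"], b["deviation"]):
                rows.append(
                    {
                        "bin": i,
                        "age_lo": b["age_lo"],
                        "age_hi": b["age_hi"],
                        "theoretical": t,
                        "ordered_residual": r,
                        "deviation": d,
                    }
                )
        return pd.DataFrame(rows)


def worm_plot_data(fit, sample, n_bins: int = 4) -> WormPlotData:
    """Worm-plot data: ordered residuals minus matched normal quantiles.

    Bins are equal-count in age (``n_bins = 1`` gives a single global
    worm).  Detrending is exact: ordered = theoretical + deviation.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ages, scores = _as_sample(sample)
    resid = quantile_residuals(fit, (ages, scores))
    edges = np.quantile(ages, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.nextafter(edges[-1], np.inf)
    data = WormPlotData()
    for b in range(n_bins):
        mask = (ages >= edges[b]) & (ages < edges[b + 1])
        r = np.sort(resid[mask])
        m = r.size
        if m == 0:
            data.bins.append(
                {
                    "age_lo": float(edges[b]),
                    "age_hi": float(edges[b + 1]),
                    "n": 0,
                    "ordered": np.array([]),
                    "theoretical": np.array([]),
                    "deviation": np.array([]),
                    "empty": True,
                }
            )
            continue
        theo = special.ndtri((np.arange(1, m + 1) - 0.5) / m)
        deviation = r - theo
        data.bins.append(
            {
                "age_lo": float(edges[b]),
                "age_hi": float(edges[b + 1]),
                "n": int(m),
                # detrending is exact by construction: ordered == theo + dev
                "ordered": theo + deviation,
                "theoretical": theo,
                "deviation": deviation,
                "empty": False,
            }
        )
    return data


def fit_three_way(sample, knots: int = 6, max_iterations: int = 2000):
    """The under/overfitting illustration triple.

    Fits (1) a very strict model — normal family, linear mu, constant
    sigma; (2) a properly fitting model — skew Student t with P-splines,
    smoothing selected by BIC; and (3) a very flexible model — the same
    but with smoothing selected by GAIC(0.1), a far weaker complexity
    penalty.  Effective df are ordered strict < BIC <= GAIC(0.1).
    """
    ages, scores = _as_sample(sample)
    if ages.size < 100:
        raise ValueError("the illustration needs a sample of at least 100")
    n = ages.size

    strict_spec = ModelSpec(
        family="normal",
        terms={"mu": TermSpec(kind="linear"), "sigma": TermSpec(kind="intercept")},
        label="strict",
        max_iterations=max_iterations,
    )

    def sst_spec(k, label):
        return ModelSpec(
            family="SST",
            terms={
                "mu": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
                "sigma": TermSpec(kind="pspline", n_knots=knots, lam="auto"),
                "nu": TermSpec(kind="intercept"),
                "tau": TermSpec(kind="intercept"),
            },
            gaic_penalty=k,
            label=label,
            max_iterations=max_iterations,
        )

    strict = NormingModel(ages, scores, strict_spec).fit()
    bic_fit = NormingModel(ages, scores, sst_spec(np.log(n), "SST[BIC]")).fit()
    flex_fit = NormingModel(ages, scores, sst_spec(0.1, "SST[GAIC(0.1)]")).fit()
    for res in (strict, bic_fit, flex_fit):
        if res.failed:
            raise ValueError(f"fit failed: {res.spec.label}: {res.message}")
    return strict, bic_fit, flex_fit


def worm_plot(data: WormPlotData, path=None, ax=None):
    """Render worm-plot panels (optional; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(data.bins)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
    for i, b in enumerate(data.bins):
        a = axes[0][i]
        if b["n"]:
            a.plot(b["theoretical"], b["deviation"], ".", ms=3)
        a.axhline(0.0, ls=":", color="k")
        a.set_title(f"age [{b['age_lo']:.1f}, {b['age_hi']:.1f})", fontsize=8)
        a.set_ylim(-1, 1)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
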