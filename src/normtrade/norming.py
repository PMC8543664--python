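"""Normed-score computation under a fitted model.

A normalized z score is the inverse-normal transform of a score's
percentile in its estimated conditional (age-specific) distribution.
Extreme estimated percentiles would map to unbounded z, so estimates are
clamped to [-5, +5] (with percentiles first clipped away from 0 and 1);
the clamp is part of the estimator and is applied everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["Z_BOUND", "NormedScore", "estimate_z", "estimate_z_grid", "centile_curves"]

Z_BOUND = 5.0
_P_EPS = 1e-15


@dataclass
class NormedScore:
    """An observed score normed against a fitted conditional distribution."""

    age: float
    score: float
    percentile: float
    z: float
    clamped: bool


def _z_from_percentile(p):
    p_clipped = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    z = special.ndtri(p_clipped)
    clamped = np.abs(z) > Z_BOUND
    return np.clip(z, -Z_BOUND, Z_BOUND), clamped


def estimate_z(fit, age, score) -> NormedScore:
    """Normalized z score of one observed score at one age.

    ``fit`` is a usable :class:`~normtrade.model.NormingResults`;
    the percentile is the fitted conditional cdf at the score and
    z = Phi^{-1}(percentile), clamped to [-5, +5].
    """
    p = float(fit.cdf(np.array([float(age)]), np.array([float(score)]))[0])
    z, clamped = _z_from_percentile(p)
    return NormedScore(
        age=float(age),
        score=float(score),
        percentile=p,
        z=float(z),
        clamped=bool(clamped),
    )


def estimate_z_grid(fit, ages, scores) -> np.ndarray:
    """Vectorized clamped z estimates for paired (age, score) arrays."""
    p = fit.cdf(np.asarray(ages, dtype=float), np.asarray(scores, dtype=float))
    z, _ = _z_from_percentile(p)
    return z


def centile_curves(fit, ages, percentiles) -> pd.DataFrame:
    """Centile table: one row per age, one column per percentile (0-100 scale).

    Scores are strictly increasing in percentile at every age.
    """
    ages = np.asarray(ages, dtype=float)
    pct = np.asarray(percentiles, dtype=float)
    if np.any((pct <= 0) | (pct >= 100)):
        raise ValueError("percentiles must lie strictly between 0 and 100")
    cols = {}
    for p in pct:
        cols[f"P{p:g}"] = fit.ppf(ages, p / 100.0)
    out = pd.DataFrame({"age": ages, **cols})
    return out
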