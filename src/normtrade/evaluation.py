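"""Monte-Carlo outcome measures: bias, variance and RMSE of z estimates.

The estimand is the population normalized z score at each cell of an
age x score grid: I ages equally spaced over the age range and J scores
placed at equally spaced population z values in [-3, +3] (so the score
grid adapts to the conditional distribution at each age).  Across R
replicate samples, each cell accumulates the estimated (clamped) z
scores, and

    bias_ij     = mean_r(zhat_ijr) - z_ij
    variance_ij = mean_r((zhat_ijr - mean_r zhat_ijr)^2)
    RMSE_ij     = sqrt(mean_r((zhat_ijr - z_ij)^2))

all with 1/R normalization, so RMSE^2 = variance + bias^2 holds exactly
in every cell.  Replicates whose fit failed outright are excluded
(per-cell effective R is tracked); fits that merely hit the iteration
cap are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import PopulationModel

__all__ = [
    "EvaluationGrid",
    "CellOutcome",
    "build_grid",
    "cell_outcomes",
    "aggregate",
]


@dataclass
class CellOutcome:
    """Bias, variance and RMSE of one (age, score) cell across replicates."""

    bias: float
    variance: float
    rmse: float
    n_replicates: int


@dataclass
class EvaluationGrid:
    """An I x J evaluation grid with replicate z-estimate accumulators."""

    ages: np.ndarray            # (I,)
    z_values: np.ndarray        # (J,)
    scores: np.ndarray          # (I, J) population scores at each z
    estimates: list = field(default_factory=list)  # list of (I, J) arrays

    @property
    def shape(self):
        return self.scores.shape

    def add_replicate(self, zhat: np.ndarray):
        zhat = np.asarray(zhat, dtype=float)
        if zhat.shape != self.shape:
            raise ValueError(f"replicate shape {zhat.shape} != grid {self.shape}")
        self.estimates.append(zhat)

    def stacked(self) -> np.ndarray:
        if not self.estimates:
            raise ValueError("no replicate estimates accumulated")
        return np.stack(self.estimates, axis=0)  # (R, I, J)

    def outcomes(self) -> dict:
        """Per-cell bias, variance, RMSE arrays (each I x J) plus R."""
        zhat = self.stacked()
        r = zhat.shape[0]
        mean = zhat.mean(axis=0)
        bias = mean - self.z_values[None, :]
        variance = ((zhat - mean[None]) ** 2).mean(axis=0)
        rmse = np.sqrt(((zhat - self.z_values[None, None, :]) ** 2).mean(axis=0))
        return {"bias": bias, "variance": variance, "rmse": rmse, "R": r}

    def to_long_frame(self) -> pd.DataFrame:
        out = self.outcomes()
        ii, jj = np.meshgrid(
            np.arange(self.ages.size), np.arange(self.z_values.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "age_index": ii.ravel(),
                "z_index": jj.ravel(),
                "age": self.ages[ii.ravel()],
                "population_z": self.z_values[jj.ravel()],
                "bias": out["bias"].ravel(),
                "variance": out["variance"].ravel(),
                "rmse": out["rmse"].ravel(),
                "R_effective": out["R"],
            }
        )


def build_grid(
    pop: PopulationModel, I: int = 1000, J: int = 100, z_range=(-3.0, 3.0)
) -> EvaluationGrid:
    """Evaluation grid for a population: I ages x J population z values."""
    if I < 2 or J < 2:
        raise ValueError("I and J must be >= 2")
    lo, hi = pop.age_range
    ages = np.linspace(lo, hi, int(I))
    z_values = np.linspace(z_range[0], z_range[1], int(J))
    age_mat = np.repeat(ages[:, None], int(J), axis=1)
    z_mat = np.repeat(z_values[None, :], int(I), axis=0)
    scores = pop.score_at_z(age_mat.ravel(), z_mat.ravel()).reshape(int(I), int(J))
    return EvaluationGrid(ages=ages, z_values=z_values, scores=scores)


def cell_outcomes(estimates, z: float) -> CellOutcome:
    """Outcomes for one cell from its replicate z estimates."""
    zhat = np.asarray(estimates, dtype=float)
    if zhat.size == 0:
        raise ValueError("at least one replicate estimate is required")
    mean = zhat.mean()
    bias = mean - z
    variance = float(((zhat - mean) ** 2).mean())
    rmse = float(np.sqrt(((zhat - z) ** 2).mean()))
    return CellOutcome(
        bias=float(bias), variance=variance, rmse=rmse, n_replicates=zhat.size
    )


def aggregate(outcomes: dict | EvaluationGrid) -> dict:
    """Unweighted grid means: mean |bias|, mean variance, mean RMSE.

    Accepts either a grid (whose outcomes are computed first) or the
    per-cell outcome dict; returns the three aggregates together with
    the per-cell tables for heat-map export.
    """
    if isinstance(outcomes, EvaluationGrid):
        outcomes = outcomes.outcomes()
    return {
        "mean_abs_bias": float(np.abs(outcomes["bias"]).mean()),
        "mean_variance": float(outcomes["variance"].mean()),
        "mean_rmse": float(outcomes["rmse"].mean()),
        "cells": outcomes,
    }
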