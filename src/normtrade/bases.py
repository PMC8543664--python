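"""Design-matrix builders: orthogonal polynomials of age and P-splines.

The longitudinal part of a norming model expresses each distributional
parameter (on its link scale) as a function of age.  Two smooth bases are
provided:

* orthogonal polynomials — orthonormalized against the sample age vector
  by QR decomposition, with the transform retained so fitted curves can
  be evaluated at arbitrary ages;
* P-splines — cubic B-splines on equally spaced knots extending beyond
  the age range, penalized by a difference penalty on adjacent
  coefficients (one smoothing parameter per term).

With the uniform extended knot grid the order-2 difference penalty has a
null space of constant plus linear functions, so the infinite-smoothing
limit of a penalized fit is exactly the least-squares straight line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["TermSpec", "TermBasis", "build_term", "poly_basis", "pspline_basis"]


@dataclass
class TermSpec:
    """Structure of one parameter's age term.

    kind: "intercept", "poly" (orthogonal polynomial), "linear", or "pspline".
    degree: polynomial degree (poly terms).
    n_knots: number of interior knots (psplines; 6 in the study design).
    spline_degree: B-spline degree (cubic by default).
    penalty_order: order of the difference penalty.
    lam: fixed smoothing parameter, or "auto" for data-driven selection.
    """

    kind: str = "intercept"
    degree: int = 0
    n_knots: int = 6
    spline_degree: int = 3
    penalty_order: int = 2
    lam: float | str = "auto"

    def __post_init__(self):
        if self.kind not in {"intercept", "poly", "linear", "pspline"}:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "poly" and self.degree < 0:
            raise ValueError("polynomial degree must be >= 0")
        if isinstance(self.lam, (int, float)) and self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TermSpec":
        return cls(**d)


@dataclass
class TermBasis:
    """A term realized on a training age vector.

    Carries the design matrix for the training ages, the penalty matrix
    (None for unpenalized terms) and everything needed to evaluate the
    basis at new ages.
    """

    spec: TermSpec
    matrix: np.ndarray
    penalty: np.ndarray | None
    _state: dict = field(default_factory=dict)

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    @property
    def penalized(self) -> bool:
        return self.penalty is not None

    def evaluate(self, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if not np.all(np.isfinite(ages)):
            raise ValueError("ages must be finite")
        kind = self.spec.kind
        if kind == "intercept":
            return np.ones((ages.size, 1))
        if kind == "linear":
            return np.column_stack([np.ones(ages.size), ages])
        if kind == "poly":
            return _poly_eval(ages, self._state)
        return _pspline_eval(ages, self._state)

    def state_dict(self) -> dict:
        out: dict[str, Any] = {"spec": self.spec.to_dict()}
        out["state"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self._state.items()
        }
        return out

    @classmethod
    def from_state(cls, d: dict) -> "TermBasis":
        spec = TermSpec.from_dict(d["spec"])
        state = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in d["state"].items()
        }
        dummy = cls(spec=spec, matrix=np.zeros((0, 1)), penalty=None, _state=state)
        if spec.kind == "pspline":
            dummy.penalty = _difference_penalty(
                int(state["n_coef"]), spec.penalty_order
            )
        return dummy


# ---------------------------------------------------------------------------
# orthogonal polynomials
# ---------------------------------------------------------------------------

def _poly_fit(ages: np.ndarray, degree: int) -> tuple[np.ndarray, dict]:
    n = ages.size
    if degree >= np.unique(ages).size:
        raise np.linalg.LinAlgError(
            f"polynomial degree {degree} needs more than {np.unique(ages).size} "
            "distinct ages"
        )
    center = ages.mean()
    scale = ages.std() if ages.std() > 0 else 1.0
    raw = np.vander((ages - center) / scale, degree + 1, increasing=True)
    q, r = np.linalg.qr(raw)
    # fix signs so the constant column is positive and degree-1 increases
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    r = r * signs[:, None]
    state = {
        "center": float(center),
        "scale": float(scale),
        "r_inv": np.linalg.inv(r),
        "degree": degree,
    }
    return q, state


def _poly_eval(ages: np.ndarray, state: dict) -> np.ndarray:
    raw = np.vander(
        (ages - state["center"]) / state["scale"],
        int(state["degree"]) + 1,
        increasing=True,
    )
    return raw @ state["r_inv"]


def poly_basis(ages, degree: int) -> np.ndarray:
    """Orthogonal-polynomial design matrix (columns mutually orthonormal).

    Column 0 spans the constant; column j is a degree-j polynomial of age
    orthogonal to all lower degrees over the sample ages.
    """
    ages = np.asarray(ages, dtype=float)
    mat, _ = _poly_fit(ages, degree)
    return mat


# ---------------------------------------------------------------------------
# P-splines
# ---------------------------------------------------------------------------

def _difference_penalty(n_coef: int, order: int) -> np.ndarray:
    d = np.eye(n_coef)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d.T @ d


def _pspline_knots(lo: float, hi: float, n_interior: int, degree: int) -> np.ndarray:
    # equally spaced knots extended beyond the boundaries (Eilers-Marx)
    n_seg = n_interior + 1
    h = (hi - lo) / n_seg
    return lo + h * np.arange(-degree, n_seg + degree + 1)


def _pspline_design(ages: np.ndarray, state: dict) -> np.ndarray:
    knots = np.asarray(state["knots"], dtype=float)
    k = int(state["spline_degree"])
    dm = BSpline.design_matrix(ages, knots, k)
    return dm.toarray()


def _pspline_eval(ages: np.ndarray, state: dict) -> np.ndarray:
    """Basis at arbitrary ages; linear extension beyond the training range."""
    lo, hi = float(state["lo"]), float(state["hi"])
    inside = np.clip(ages, lo, hi)
    mat = _pspline_design(inside, state)
    below = ages < lo
    above = ages > hi
    if below.any():
        mat[below] += np.outer(ages[below] - lo, _pspline_deriv_row(lo, state))
    if above.any():
        mat[above] += np.outer(ages[above] - hi, _pspline_deriv_row(hi, state))
    return mat


def _pspline_deriv_row(x: float, state: dict) -> np.ndarray:
    knots = np.asarray(state["knots"], dtype=float)
    k = int(state["spline_degree"])
    n_coef = int(state["n_coef"])
    row = np.empty(n_coef)
    for j in range(n_coef):
        coef = np.zeros(n_coef)
        coef[j] = 1.0
        row[j] = BSpline(knots, coef, k, extrapolate=True).derivative()(x)
    return row


def _pspline_fit(ages: np.ndarray, spec: TermSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    lo, hi = float(ages.min()), float(ages.max())
    if hi <= lo:
        raise np.linalg.LinAlgError("degenerate age support for a P-spline term")
    knots = _pspline_knots(lo, hi, spec.n_knots, spec.spline_degree)
    n_coef = len(knots) - spec.spline_degree - 1
    state = {
        "knots": knots,
        "spline_degree": spec.spline_degree,
        "n_coef": n_coef,
        "lo": lo,
        "hi": hi,
    }
    mat = _pspline_design(ages, state)
    pen = _difference_penalty(n_coef, spec.penalty_order)
    return mat, pen, state


def pspline_basis(ages, spec: TermSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """B-spline design matrix and difference-penalty matrix for ``ages``.

    Rows of the design matrix sum to 1 on the training range; the penalty
    is positive semidefinite with null-space dimension ``penalty_order``.
    """
    ages = np.asarray(ages, dtype=float)
    if spec is None:
        spec = TermSpec(kind="pspline")
    mat, pen, _ = _pspline_fit(ages, spec)
    return mat, pen


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def build_term(ages, spec: TermSpec) -> TermBasis:
    """Realize a TermSpec on a training age vector."""
    ages = np.asarray(ages, dtype=float)
    if spec.kind == "intercept":
        return TermBasis(spec, np.ones((ages.size, 1)), None)
    if spec.kind == "linear":
        return TermBasis(spec, np.column_stack([np.ones(ages.size), ages]), None)
    if spec.kind == "poly":
        mat, state = _poly_fit(ages, spec.degree)
        return TermBasis(spec, mat, None, state)
    mat, pen, state = _pspline_fit(ages, spec)
    return TermBasis(spec, mat, pen, state)
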