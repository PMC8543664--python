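"""Distribution families for distributional-regression norming.

Three families are supported:

* ``SST`` — the skew Student *t*, a Fernandez–Steel skewed *t* rescaled so
  that ``mu`` is the mean and ``sigma`` the standard deviation of the
  distribution.  ``nu > 0`` controls skewness (``nu = 1`` is symmetric,
  ``nu < 1`` skews left) and ``tau > 2`` is a degrees-of-freedom-like tail
  parameter; the family converges to the normal as ``nu -> 1``,
  ``tau -> inf``.
* ``BCPE`` — the Box–Cox Power Exponential: a Box–Cox transform of the
  (positive) score followed by a standardized power-exponential kernel,
  with the exact truncation normalizer for the positive support.  ``mu``
  is (approximately) the median, ``sigma`` the coefficient of variation,
  ``nu`` the Box–Cox skewness power and ``tau`` the kurtosis power
  (``tau = 2`` gives the Box–Cox normal).
* ``normal`` — the Gaussian, used for the exactly-normal population and
  estimation variants (rather than SST with a huge ``tau``).

All distribution methods broadcast over observations, so conditional
models with age-varying parameters evaluate in a single vectorized call.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
from scipy import special

__all__ = [
    "DistParams",
    "Link",
    "IdentityLink",
    "LogLink",
    "ShiftedLogLink",
    "LINKS",
    "Family",
    "SST",
    "BCPE",
    "NormalFamily",
    "get_family",
    "density",
    "cdf",
    "quantile",
    "sample",
    "link_apply",
    "link_invert",
]

_SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------

class Link:
    """Strictly monotone bijection from a parameter range to the real line."""

    name = "link"

    def apply(self, value):
        raise NotImplementedError

    def invert(self, eta):
        raise NotImplementedError


class IdentityLink(Link):
    name = "identity"

    def apply(self, value):
        return np.asarray(value, dtype=float)

    def invert(self, eta):
        return np.asarray(eta, dtype=float)


class LogLink(Link):
    name = "log"

    def apply(self, value):
        value = np.asarray(value, dtype=float)
        if np.any(value <= 0):
            raise ValueError("log link requires a strictly positive parameter")
        return np.log(value)

    def invert(self, eta):
        return np.exp(np.asarray(eta, dtype=float))


class ShiftedLogLink(Link):
    """``ln(value - shift)``; used for the SST tail parameter (shift 2)."""

    def __init__(self, shift: float = 2.0):
        self.shift = float(shift)
        self.name = f"log(x-{self.shift:g})"

    def apply(self, value):
        value = np.asarray(value, dtype=float)
        if np.any(value <= self.shift):
            raise ValueError(f"shifted-log link requires value > {self.shift:g}")
        return np.log(value - self.shift)

    def invert(self, eta):
        return self.shift + np.exp(np.asarray(eta, dtype=float))


LINKS: Mapping[str, Link] = {
    "identity": IdentityLink(),
    "log": LogLink(),
    "log-2": ShiftedLogLink(2.0),
}


def link_apply(link: str | Link, value):
    """Map a parameter value to the (unconstrained) link scale."""
    if isinstance(link, str):
        link = LINKS[link]
    return link.apply(value)


def link_invert(link: str | Link, eta):
    """Map a link-scale value back to the parameter's natural range."""
    if isinstance(link, str):
        link = LINKS[link]
    return link.invert(eta)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class DistParams:
    """The four distributional parameters of a conditional score distribution.

    ``mu`` (location, raw-score units), ``sigma`` (scale > 0), ``nu``
    (skewness, dimensionless) and ``tau`` (kurtosis, dimensionless).  The
    normal family ignores ``nu`` and ``tau``.
    """

    mu: float
    sigma: float
    nu: float = 1.0
    tau: float = 10.0

    def as_dict(self, family: str | None = None) -> dict:
        d = asdict(self)
        if family is not None:
            d = {"family": family, **d}
        return d


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def _t_logpdf(x, df):
    return (
        special.gammaln((df + 1.0) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * np.log(np.pi * df)
        - (df + 1.0) / 2.0 * np.log1p(x * x / df)
    )


def _t_cdf(x, df):
    return special.stdtr(df, x)


def _t_ppf(q, df):
    return special.stdtrit(df, q)


class Family:
    """Interface of a four-parameter (or fewer) distribution family."""

    name = "family"
    n_params = 4
    param_names = ("mu", "sigma", "nu", "tau")
    default_links: tuple[str, ...] = ("identity", "log", "log", "log")

    def _validate(self, mu, sigma, nu, tau):
        if np.any(~np.isfinite(np.asarray(mu, dtype=float))):
            raise ValueError(f"{self.name}: mu must be finite")
        if np.any(np.asarray(sigma, dtype=float) <= 0):
            raise ValueError(f"{self.name}: sigma must be > 0")

    def logpdf(self, x, mu, sigma, nu=1.0, tau=10.0):
        raise NotImplementedError

    def pdf(self, x, mu, sigma, nu=1.0, tau=10.0):
        return np.exp(self.logpdf(x, mu, sigma, nu, tau))

    def cdf(self, x, mu, sigma, nu=1.0, tau=10.0):
        raise NotImplementedError

    def ppf(self, q, mu, sigma, nu=1.0, tau=10.0):
        raise NotImplementedError

    def rvs(self, mu, sigma, nu=1.0, tau=10.0, size=None, rng=None):
        """Inverse-cdf sampling from uniform draws (reproducible by ``rng``)."""
        rng = np.random.default_rng(rng)
        u = rng.uniform(size=size)
        return self.ppf(u, mu, sigma, nu, tau)

    # starting values for the fitting engine, on the natural scale
    init_params = DistParams(0.0, 1.0, 1.0, 10.0)

    def support_ok(self, x) -> bool:
        return bool(np.all(np.isfinite(x)))


class SST(Family):
    """Skew Student *t*, standardized so mu is the mean and sigma the SD.

    A Fernandez–Steel skewed *t* variable ``X`` with skew factor ``nu`` and
    ``tau`` degrees of freedom has density

        f(z) = c * t_tau(z * nu)    for z < 0,
        f(z) = c * t_tau(z / nu)    for z >= 0,      c = 2 / (nu + 1/nu),

    with mean ``m`` and standard deviation ``s`` available in closed form
    for ``tau > 2``.  The SST variate is ``Y = mu + sigma * (X - m) / s``.
    """

    name = "SST"
    n_params = 4
    default_links = ("identity", "log", "log", "log-2")
    init_params = DistParams(0.0, 1.0, 1.0, 3.0)

    def _validate(self, mu, sigma, nu, tau):
        super()._validate(mu, sigma, nu, tau)
        if np.any(np.asarray(nu, dtype=float) <= 0):
            raise ValueError("SST: nu must be > 0")
        if np.any(np.asarray(tau, dtype=float) <= 2):
            raise ValueError("SST: tau must be > 2")

    @staticmethod
    def _skew_moments(nu, tau):
        """Mean and SD of the unit Fernandez–Steel skew-t variable."""
        nu = np.asarray(nu, dtype=float)
        tau = np.asarray(tau, dtype=float)
        # E|T| for Student t with tau df (tau > 1)
        abs_m = np.exp(
            0.5 * np.log(tau)
            + special.gammaln((tau + 1.0) / 2.0)
            - special.gammaln(tau / 2.0)
            - 0.5 * np.log(np.pi)
            + np.log(2.0)
            - np.log(tau - 1.0)
        )
        m1 = abs_m / 2.0
        m2 = tau / (tau - 2.0)
        c = 2.0 / (nu + 1.0 / nu)
        mean = c * m1 * (nu**2 - nu**-2)
        ex2 = m2 * (nu**3 + nu**-3) / (nu + 1.0 / nu)
        sd = np.sqrt(ex2 - mean**2)
        return mean, sd

    def _standardize(self, x, mu, sigma, nu, tau):
        m, s = self._skew_moments(nu, tau)
        z = m + s * (np.asarray(x, dtype=float) - mu) / sigma
        return z, m, s

    def logpdf(self, x, mu, sigma, nu=1.0, tau=10.0):
        self._validate(mu, sigma, nu, tau)
        nu = np.asarray(nu, dtype=float)
        z, _, s = self._standardize(x, mu, sigma, nu, tau)
        arg = np.where(z < 0, z * nu, z / nu)
        logc = np.log(2.0) - np.log(nu + 1.0 / nu)
        return logc + _t_logpdf(arg, tau) + np.log(s) - np.log(sigma)

    def cdf(self, x, mu, sigma, nu=1.0, tau=10.0):
        self._validate(mu, sigma, nu, tau)
        nu = np.asarray(nu, dtype=float)
        z, _, _ = self._standardize(x, mu, sigma, nu, tau)
        nu2 = nu * nu
        lower = 2.0 / (1.0 + nu2) * _t_cdf(z * nu, tau)
        upper = 1.0 / (1.0 + nu2) + 2.0 * nu2 / (1.0 + nu2) * (
            _t_cdf(z / nu, tau) - 0.5
        )
        return np.where(z < 0, lower, upper)

    def ppf(self, q, mu, sigma, nu=1.0, tau=10.0):
        self._validate(mu, sigma, nu, tau)
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("SST: probability must lie in (0, 1)")
        nu = np.asarray(nu, dtype=float)
        tau = np.asarray(tau, dtype=float)
        nu2 = nu * nu
        q0 = 1.0 / (1.0 + nu2)  # cdf at the mode-side split point z = 0
        p_low = np.minimum(q * (1.0 + nu2) / 2.0, 1.0 - 1e-16)
        z_low = _t_ppf(p_low, tau) / nu
        p_high = np.clip((q - q0) * (1.0 + nu2) / (2.0 * nu2) + 0.5, 1e-16, 1 - 1e-16)
        z_high = nu * _t_ppf(p_high, tau)
        z = np.where(q < q0, z_low, z_high)
        m, s = self._skew_moments(nu, tau)
        return mu + sigma * (z - m) / s


class NormalFamily(Family):
    """Gaussian family; the exact nu = 1, tau = inf limit of the SST."""

    name = "normal"
    n_params = 2
    param_names = ("mu", "sigma")
    default_links = ("identity", "log")
    init_params = DistParams(0.0, 1.0)

    def logpdf(self, x, mu, sigma, nu=1.0, tau=10.0):
        self._validate(mu, sigma, nu, tau)
        z = (np.asarray(x, dtype=float) - mu) / sigma
        return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi) - np.log(sigma)

    def cdf(self, x, mu, sigma, nu=1.0, tau=10.0):
        self._validate(mu, sigma, nu, tau)
        z = (np.asarray(x, dtype=float) - mu) / sigma
        return special.ndtr(z)

    def ppf(self, q, mu, sigma, nu=1.0, tau=10.0):
        self._validate(mu, sigma, nu, tau)
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("normal: probability must lie in (0, 1)")
        return mu + sigma * special.ndtri(q)


class BCPE(Family):
    """Box–Cox Power Exponential on positive support.

    ``z = ((y / mu)**nu - 1) / (sigma * nu)`` (log form at ``nu = 0``) is
    modelled as a standardized power-exponential variable with kurtosis
    power ``tau``; the density is renormalized for the truncation of the
    transform to ``y > 0``.
    """

    name = "BCPE"
    n_params = 4
    default_links = ("identity", "log", "identity", "log")
    init_params = DistParams(1.0, 0.1, 1.0, 2.0)

    def _validate(self, mu, sigma, nu, tau):
        super()._validate(mu, sigma, nu, tau)
        if np.any(np.asarray(mu, dtype=float) <= 0):
            raise ValueError("BCPE: mu must be > 0")
        if np.any(np.asarray(tau, dtype=float) <= 0):
            raise ValueError("BCPE: tau must be > 0")

    # --- standardized power exponential kernel (mean 0, variance 1) ---

    @staticmethod
    def _pe_c(tau):
        return np.exp(0.5 * (special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau)))

    @classmethod
    def _pe_logpdf(cls, t, tau):
        c = cls._pe_c(tau)
        return (
            np.log(tau)
            - np.log(2.0 * c)
            - special.gammaln(1.0 / tau)
            - np.abs(t / c) ** tau
        )

    @classmethod
    def _pe_cdf(cls, t, tau):
        c = cls._pe_c(tau)
        g = special.gammainc(1.0 / tau, np.abs(t / c) ** tau)
        return 0.5 * (1.0 + np.sign(t) * g)

    @classmethod
    def _pe_ppf(cls, p, tau):
        c = cls._pe_c(tau)
        u = 2.0 * np.asarray(p, dtype=float) - 1.0
        mag = c * special.gammaincinv(1.0 / tau, np.abs(u)) ** (1.0 / tau)
        return np.sign(u) * mag

    # --- Box-Cox transform ---

    @staticmethod
    def _bc_z(y, mu, sigma, nu):
        y = np.asarray(y, dtype=float)
        ratio = y / mu
        nu_arr = np.asarray(nu, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_pow = (np.power(ratio, np.where(nu_arr == 0, 1.0, nu_arr)) - 1.0) / (
                sigma * np.where(nu_arr == 0, 1.0, nu_arr)
            )
            z_log = np.log(ratio) / np.asarray(sigma, dtype=float)
        return np.where(nu_arr == 0, z_log, z_pow)

    def _trunc_norm(self, sigma, nu, tau):
        """P(|T| < 1/(sigma |nu|)): mass retained by the y > 0 truncation."""
        nu_arr = np.asarray(nu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        with np.errstate(divide="ignore"):
            bound = np.where(nu_arr == 0, np.inf, 1.0 / (sigma * np.abs(nu_arr)))
        return self._pe_cdf(bound, tau)

    def logpdf(self, x, mu, sigma, nu=1.0, tau=2.0):
        self._validate(mu, sigma, nu, tau)
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("BCPE: scores must be > 0")
        z = self._bc_z(x, mu, sigma, nu)
        nu_arr = np.asarray(nu, dtype=float)
        norm = self._trunc_norm(sigma, nu, tau)
        return (
            (nu_arr - 1.0) * np.log(x)
            - nu_arr * np.log(mu)
            - np.log(sigma)
            + self._pe_logpdf(z, tau)
            - np.log(norm)
        )

    def cdf(self, x, mu, sigma, nu=1.0, tau=2.0):
        self._validate(mu, sigma, nu, tau)
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("BCPE: scores must be > 0")
        z = self._bc_z(x, mu, sigma, nu)
        nu_arr = np.asarray(nu, dtype=float)
        f_z = self._pe_cdf(z, tau)
        norm = self._trunc_norm(sigma, nu, tau)
        # nu > 0: truncated below at z = -1/(sigma nu); nu < 0: above.
        p_pos = (f_z - (1.0 - norm)) / norm
        p_neg = f_z / norm
        out = np.where(nu_arr > 0, p_pos, np.where(nu_arr < 0, p_neg, f_z))
        return np.clip(out, 0.0, 1.0)

    def ppf(self, q, mu, sigma, nu=1.0, tau=2.0):
        self._validate(mu, sigma, nu, tau)
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("BCPE: probability must lie in (0, 1)")
        nu_arr = np.asarray(nu, dtype=float)
        norm = self._trunc_norm(sigma, nu, tau)
        p = np.where(
            nu_arr > 0,
            q * norm + (1.0 - norm),
            np.where(nu_arr < 0, q * norm, q),
        )
        z = self._pe_ppf(np.clip(p, 1e-16, 1 - 1e-16), tau)
        sig = np.asarray(sigma, dtype=float)
        with np.errstate(invalid="ignore"):
            y_pow = mu * np.power(
                np.maximum(1.0 + sig * np.where(nu_arr == 0, 1.0, nu_arr) * z, 1e-300),
                1.0 / np.where(nu_arr == 0, 1.0, nu_arr),
            )
            y_log = mu * np.exp(sig * z)
        return np.where(nu_arr == 0, y_log, y_pow)


_FAMILIES = {"SST": SST(), "BCPE": BCPE(), "normal": NormalFamily()}


def get_family(name: str | Family) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; expected one of {sorted(_FAMILIES)}")


# ---------------------------------------------------------------------------
# functional surface over DistParams
# ---------------------------------------------------------------------------

def _unpack(p: DistParams):
    return p.mu, p.sigma, p.nu, p.tau


def density(family, x, p: DistParams):
    """Density of ``family`` at score ``x`` under parameters ``p``."""
    f = get_family(family)
    return f.pdf(x, *_unpack(p))


def cdf(family, x, p: DistParams):
    """Cumulative probability of score ``x``."""
    f = get_family(family)
    return f.cdf(x, *_unpack(p))


def quantile(family, q, p: DistParams):
    """Score at cumulative probability ``q`` (0 < q < 1)."""
    f = get_family(family)
    return f.ppf(q, *_unpack(p))


def sample(family, p: DistParams, n: int, seed=None):
    """Draw ``n`` scores by inverse-cdf sampling; reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    f = get_family(family)
    return f.rvs(*_unpack(p), size=int(n), rng=seed)
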