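"""Right-skewed parametric families and the generalized Pareto distribution.

Provides a single frozen-spec abstraction (:class:`DistributionSpec`) with
density, CDF, quantile and sampling for the four positive families used to
model the bulk of contaminant concentrations (lognormal, Weibull, gamma,
exponential) plus the generalized Pareto distribution (GPD) used for
exceedances over a high threshold.  Maximum-likelihood fitting returns a
:class:`FitResult` carrying the achieved log-likelihood and information
criteria.

Conventions
-----------
* gamma is parameterized internally as (shape, rate); ``scale`` is accepted
  at construction and converted.
* the GPD parameter vector is (shape xi, scale sigma, location u); the
  ``|xi| < 1e-8`` branch switches to the exponential-limit formulas.
* samplers take an explicit ``seed`` (int or ``numpy.random.Generator``);
  there is no module-level RNG state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from ._utils import FitError, ValidationError, as_rng

__all__ = ["Family", "DistributionSpec", "FitResult", "fit_mle"]

#: below this |xi| the GPD is evaluated with its exponential-limit formulas
XI_EPS = 1e-8


class Family(str, enum.Enum):
    LOGNORMAL = "lognormal"
    WEIBULL = "weibull"
    GAMMA = "gamma"
    EXPONENTIAL = "exponential"
    GPD = "gpd"


_PARAM_NAMES: dict[Family, tuple[str, ...]] = {
    Family.LOGNORMAL: ("log_mean", "log_sd"),
    Family.WEIBULL: ("shape", "scale"),
    Family.GAMMA: ("shape", "rate"),
    Family.EXPONENTIAL: ("rate",),
    Family.GPD: ("shape", "scale", "loc"),
}

#: number of free parameters counted in AIC/BIC for each family
FAMILY_K: dict[Family, int] = {
    Family.LOGNORMAL: 2,
    Family.WEIBULL: 2,
    Family.GAMMA: 2,
    Family.EXPONENTIAL: 1,
    Family.GPD: 2,  # location is the (known) threshold, not estimated here
}


@dataclass(frozen=True)
class DistributionSpec:
    """A frozen distribution: family tag plus ordered parameter vector."""

    family: Family
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        names = _PARAM_NAMES[fam]
        if len(params) != len(names):
            raise ValidationError(
                f"{fam.value} expects {len(names)} parameters {names}, got {len(params)}"
            )
        if not all(math.isfinite(p) for p in params):
            raise ValidationError(f"non-finite parameter in {params}")
        if fam is Family.LOGNORMAL:
            if params[1] <= 0:
                raise ValidationError("lognormal log_sd must be > 0")
        elif fam in (Family.WEIBULL, Family.GAMMA):
            if params[0] <= 0 or params[1] <= 0:
                raise ValidationError(f"{fam.value} parameters must be > 0")
        elif fam is Family.EXPONENTIAL:
            if params[0] <= 0:
                raise ValidationError("exponential rate must be > 0")
        elif fam is Family.GPD:
            if params[1] <= 0:
                raise ValidationError("gpd scale must be > 0")

    # -- constructors ------------------------------------------------------
    @classmethod
    def lognormal(cls, log_mean: float, log_sd: float) -> "DistributionSpec":
        return cls(Family.LOGNORMAL, (log_mean, log_sd))

    @classmethod
    def weibull(cls, shape: float, scale: float) -> "DistributionSpec":
        return cls(Family.WEIBULL, (shape, scale))

    @classmethod
    def gamma(
        cls, shape: float, rate: float | None = None, *, scale: float | None = None
    ) -> "DistributionSpec":
        if (rate is None) == (scale is None):
            raise ValidationError("give exactly one of rate or scale")
        if rate is None:
            if scale <= 0:
                raise ValidationError("gamma scale must be > 0")
            rate = 1.0 / scale
        return cls(Family.GAMMA, (shape, rate))

    @classmethod
    def exponential(cls, rate: float) -> "DistributionSpec":
        return cls(Family.EXPONENTIAL, (rate,))

    @classmethod
    def gpd(cls, shape: float, scale: float, loc: float = 0.0) -> "DistributionSpec":
        return cls(Family.GPD, (shape, scale, loc))

    # -- introspection -----------------------------------------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.family]

    def param(self, name: str) -> float:
        return self.params[self.param_names.index(name)]

    @property
    def k(self) -> int:
        return FAMILY_K[self.family]

    def as_dict(self) -> dict:
        return {
            "family": self.family.value,
            "params": dict(zip(self.param_names, self.params)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        fam = Family(d["family"])
        names = _PARAM_NAMES[fam]
        return cls(fam, tuple(d["params"][n] for n in names))

    def support(self) -> tuple[float, float]:
        if self.family is Family.GPD:
            xi, sigma, u = self.params
            upper = math.inf if xi >= -XI_EPS else u - sigma / xi
            return (u, upper)
        return (0.0, math.inf)

    # -- evaluation --------------------------------------------------------
    # direct formulas (no scipy frozen-distribution objects: their per-call
    # construction cost dominates bootstrap loops)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        f = self.family
        with np.errstate(divide="ignore", invalid="ignore"):
            if f is Family.GPD:
                out = np.log(_gpd_pdf(x, *self.params))
            elif f is Family.LOGNORMAL:
                mu, sd = self.params
                logx = np.log(np.where(x > 0, x, np.nan))
                out = np.where(
                    x > 0,
                    -logx - math.log(sd) - 0.5 * math.log(2 * math.pi)
                    - (logx - mu) ** 2 / (2 * sd * sd),
                    -np.inf,
                )
            elif f is Family.WEIBULL:
                k, lam = self.params
                z = np.where(x >= 0, x / lam, np.nan)
                out = np.where(
                    x >= 0,
                    math.log(k / lam) + (k - 1.0) * np.log(z) - z ** k,
                    -np.inf,
                )
                if k == 1.0:  # avoid 0*log(0) at the origin
                    out = np.where(x == 0, math.log(k / lam), out)
            elif f is Family.GAMMA:
                a, r = self.params
                out = np.where(
                    x > 0,
                    a * math.log(r) - special.gammaln(a)
                    + (a - 1.0) * np.log(np.where(x > 0, x, np.nan)) - r * x,
                    -np.inf,
                )
                if a == 1.0:
                    out = np.where(x == 0, math.log(r), out)
            else:  # exponential
                r = self.params[0]
                out = np.where(x >= 0, math.log(r) - r * x, -np.inf)
        out = np.asarray(out, dtype=float)
        return out if out.ndim else float(out)

    def pdf(self, x):
        lp = np.asarray(self.logpdf(x), dtype=float)
        with np.errstate(over="ignore"):
            out = np.exp(lp)
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        f = self.family
        if f is Family.GPD:
            out = _gpd_cdf(x, *self.params)
        elif f is Family.LOGNORMAL:
            mu, sd = self.params
            out = np.where(
                x > 0,
                special.ndtr((np.log(np.where(x > 0, x, 1.0)) - mu) / sd),
                0.0,
            )
        elif f is Family.WEIBULL:
            k, lam = self.params
            out = np.where(x > 0, -np.expm1(-np.where(x > 0, x / lam, 0.0) ** k), 0.0)
        elif f is Family.GAMMA:
            a, r = self.params
            out = np.where(x > 0, special.gammainc(a, r * np.maximum(x, 0.0)), 0.0)
        else:  # exponential
            out = np.where(x > 0, -np.expm1(-self.params[0] * np.maximum(x, 0.0)), 0.0)
        out = np.asarray(out, dtype=float)
        return out if out.ndim else float(out)

    def quantile(self, p):
        p_arr = np.asarray(p, dtype=float)
        if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
            raise ValidationError("quantile probability must lie strictly in (0, 1)")
        f = self.family
        if f is Family.GPD:
            out = _gpd_ppf(p_arr, *self.params)
        elif f is Family.LOGNORMAL:
            mu, sd = self.params
            out = np.exp(mu + sd * special.ndtri(p_arr))
        elif f is Family.WEIBULL:
            k, lam = self.params
            out = lam * (-np.log1p(-p_arr)) ** (1.0 / k)
        elif f is Family.GAMMA:
            a, r = self.params
            out = special.gammaincinv(a, p_arr) / r
        else:
            out = -np.log1p(-p_arr) / self.params[0]
        out = np.asarray(out, dtype=float)
        return out if out.ndim else float(out)

    def mean(self) -> float:
        f = self.family
        if f is Family.GPD:
            xi, sigma, u = self.params
            return u + sigma / (1.0 - xi) if xi < 1.0 else math.inf
        if f is Family.LOGNORMAL:
            mu, sd = self.params
            return math.exp(mu + 0.5 * sd * sd)
        if f is Family.WEIBULL:
            k, lam = self.params
            return lam * math.gamma(1.0 + 1.0 / k)
        if f is Family.GAMMA:
            a, r = self.params
            return a / r
        return 1.0 / self.params[0]

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        if n < 1:
            raise ValidationError("n must be >= 1")
        rng = as_rng(seed)
        f = self.family
        if f is Family.GPD:
            return _gpd_ppf(rng.uniform(size=n), *self.params)
        if f is Family.LOGNORMAL:
            mu, sd = self.params
            return np.exp(rng.normal(mu, sd, size=n))
        if f is Family.WEIBULL:
            k, lam = self.params
            return lam * rng.weibull(k, size=n)
        if f is Family.GAMMA:
            a, r = self.params
            return rng.gamma(a, 1.0 / r, size=n)
        return rng.exponential(1.0 / self.params[0], size=n)


# ---------------------------------------------------------------------------
# GPD primitives (explicit, with a guarded exponential-limit branch at xi=0)
# ---------------------------------------------------------------------------

def _gpd_cdf(x, xi, sigma, u):
    x = np.asarray(x, dtype=float)
    shape = x.shape
    z = np.atleast_1d((x - u) / sigma)
    out = np.zeros_like(z)
    pos = z > 0
    if abs(xi) < XI_EPS:
        out[pos] = -np.expm1(-z[pos])
    elif xi > 0:
        out[pos] = -np.expm1(np.log1p(xi * z[pos]) * (-1.0 / xi))
    else:
        zb = np.minimum(z, -1.0 / xi)  # CDF = 1 beyond the finite endpoint
        with np.errstate(divide="ignore"):
            out[pos] = -np.expm1(np.log1p(xi * zb[pos]) * (-1.0 / xi))
    return out.reshape(shape)


def _gpd_pdf(x, xi, sigma, u):
    x = np.asarray(x, dtype=float)
    shape = x.shape
    z = np.atleast_1d((x - u) / sigma)
    out = np.zeros_like(z)
    if abs(xi) < XI_EPS:
        ok = z >= 0
        out[ok] = np.exp(-z[ok]) / sigma
    else:
        ok = (z >= 0) & (1.0 + xi * z > 0)
        out[ok] = np.exp(np.log1p(xi * z[ok]) * (-1.0 / xi - 1.0)) / sigma
    return out.reshape(shape)


def _gpd_logpdf(x, xi, sigma):
    """log density of exceedances x >= 0 with location 0; -inf off support."""
    x = np.asarray(x, dtype=float)
    z = x / sigma
    if abs(xi) < XI_EPS:
        out = np.where(z >= 0, -z - math.log(sigma), -np.inf)
    else:
        with np.errstate(invalid="ignore"):
            t = 1.0 + xi * z
            out = np.where(
                (z >= 0) & (t > 0),
                np.log1p(xi * z) * (-1.0 / xi - 1.0) - math.log(sigma),
                -np.inf,
            )
    return out


def _gpd_ppf(p, xi, sigma, u):
    p = np.asarray(p, dtype=float)
    with np.errstate(over="ignore"):  # heavy tails may overflow to inf near p=1
        if abs(xi) < XI_EPS:
            q = -sigma * np.log1p(-p)
        else:
            q = sigma / xi * np.expm1(-xi * np.log1p(-p))
    return u + q


# ---------------------------------------------------------------------------
# Weighted MLE primitives (weights=1 gives ordinary MLE; reused by EM)
# ---------------------------------------------------------------------------

def lognormal_mle(x: np.ndarray, w: np.ndarray | None = None) -> tuple[float, float]:
    logx = np.log(x)
    if w is None:
        mu = float(np.mean(logx))
        sd = float(np.std(logx))
    else:
        sw = w.sum()
        mu = float(np.dot(w, logx) / sw)
        sd = float(math.sqrt(np.dot(w, (logx - mu) ** 2) / sw))
    if sd <= 0:
        raise FitError("degenerate lognormal fit: zero log-variance")
    return mu, sd


def gamma_mle(x: np.ndarray, w: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted gamma MLE (shape, rate) via the digamma equation."""
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    m = float(np.dot(w, x) / sw)
    s = math.log(m) - float(np.dot(w, np.log(x)) / sw)
    if s <= 0:
        raise FitError("degenerate gamma fit: zero log-dispersion")
    # Minka-style initial value, then Newton on log(a) - psi(a) = s
    a = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        f = math.log(a) - special.digamma(a) - s
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(a), float(a / m)


def weibull_mle(x: np.ndarray, w: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted Weibull MLE (shape, scale) via the 1-D profile equation."""
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    logx = np.log(x)
    mlog = float(np.dot(w, logx) / sw)

    def eq(k: float) -> float:
        # center before exponentiating so large k cannot overflow
        xk = np.exp(k * (logx - logx.max()))
        return float(np.dot(w, xk * logx) / np.dot(w, xk)) - 1.0 / k - mlog

    sd_log = math.sqrt(max(float(np.dot(w, (logx - mlog) ** 2) / sw), 1e-12))
    k0 = max(math.pi / (math.sqrt(6.0) * sd_log), 1e-2)
    lo, hi = k0, k0
    for _ in range(80):
        if eq(lo) < 0:
            break
        lo /= 1.6
        if lo < 1e-6:
            raise FitError("weibull shape bracket failed (low)")
    for _ in range(80):
        if eq(hi) > 0:
            break
        hi *= 1.6
        if hi > 1e6:
            raise FitError("weibull shape bracket failed (high)")
    k = optimize.brentq(eq, lo, hi, xtol=1e-12, rtol=1e-12)
    scale = float(np.dot(w, np.exp(k * logx)) / sw) ** (1.0 / k)
    return float(k), float(scale)


def gpd_mle(
    exceedances: np.ndarray, *, xi0: float = 0.1, sigma0: float | None = None
) -> tuple[float, float, bool]:
    """MLE of GPD (shape, scale) for exceedances over a known threshold (loc 0)."""
    y = np.asarray(exceedances, dtype=float)
    if y.size < 2:
        raise FitError("GPD fit needs at least 2 exceedances")
    if np.any(y < 0):
        raise ValidationError("exceedances must be >= 0")
    if sigma0 is None:
        sigma0 = float(np.std(y)) or float(np.mean(y)) or 1.0

    def nll(theta):
        xi, logsig = theta
        if not -5.0 < xi < 10.0 or abs(logsig) > 50.0:
            return 1e12
        ll = _gpd_logpdf(y, xi, math.exp(logsig))
        s = ll.sum()
        return -s if np.isfinite(s) else 1e12

    res = optimize.minimize(
        nll, x0=[xi0, math.log(sigma0)], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    xi, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    return xi, sigma, bool(res.success)


# ---------------------------------------------------------------------------
# Fit result + MLE front door
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    spec: DistributionSpec
    loglik: float
    n: int
    k: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2.0 * self.loglik

    def as_dict(self) -> dict:
        return {
            "spec": self.spec.as_dict(),
            "loglik": self.loglik,
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
            "aic": self.aic,
            "bic": self.bic,
        }


def _validate_positive(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("data must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValidationError("data must be finite and strictly positive")
    return x


def fit_mle(data, family: Family | str) -> FitResult:
    """Maximum-likelihood fit of one parametric family to positive data.

    For the GPD the data are interpreted as exceedances over a zero
    threshold (location fixed at 0, not counted in ``k``).
    """
    family = Family(family)
    x = _validate_positive(data)
    if x.size < 3:
        raise ValidationError("need at least 3 observations to fit")
    converged = True
    if family is Family.LOGNORMAL:
        spec = DistributionSpec.lognormal(*lognormal_mle(x))
    elif family is Family.EXPONENTIAL:
        spec = DistributionSpec.exponential(1.0 / float(np.mean(x)))
    elif family is Family.GAMMA:
        spec = DistributionSpec.gamma(*gamma_mle(x))
    elif family is Family.WEIBULL:
        spec = DistributionSpec.weibull(*weibull_mle(x))
    elif family is Family.GPD:
        xi, sigma, converged = gpd_mle(x)
        spec = DistributionSpec.gpd(xi, sigma, 0.0)
    else:  # pragma: no cover
        raise ValidationError(f"unknown family {family}")
    ll = float(np.sum(spec.logpdf(x)))
    if not math.isfinite(ll):
        converged = False
    return FitResult(spec=spec, loglik=ll, n=int(x.size), k=spec.k, converged=converged)
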