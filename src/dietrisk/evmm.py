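"""Spliced bulk + generalized-Pareto tail model.

The model places a parametric bulk distribution H(.|eta) below a threshold
``u`` and a GPD for exceedances above it, with the tail fraction tied to the
bulk model::

    F(x) = H(x|eta)                                   x <  u
    F(x) = H(u|eta) + (1 - H(u|eta)) G(x|xi,sigma,u)  x >= u

so the CDF is continuous at the threshold by construction (G(u) = 0).  The
threshold is treated as an estimated parameter: a profile search over a grid
of sample quantiles, each with a continuous joint MLE of (eta, xi, sigma),
followed by local refinement of ``u`` between the best grid neighbours.

An alternative parameterised-tail-fraction variant (free phi with the bulk
renormalised below u) is available via ``tail_fraction="free"`` for
sensitivity analysis; the default is the bulk-based form above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._utils import FitError, ValidationError, as_rng
from .distributions import (
    XI_EPS,
    DistributionSpec,
    Family,
    _gpd_cdf,
    _gpd_logpdf,
    _gpd_pdf,
    _gpd_ppf,
    gamma_mle,
    lognormal_mle,
    weibull_mle,
)

__all__ = ["EvmmSpec", "EvmmFitResult", "evmm_fit", "DEFAULT_THRESHOLD_GRID"]

#: profile-search grid over candidate thresholds, in percentile points
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(np.arange(50.0, 95.0 + 1e-9, 2.5))

_BULK_FAMILIES = (Family.LOGNORMAL, Family.WEIBULL, Family.GAMMA)


@dataclass(frozen=True)
class EvmmSpec:
    """Bulk distribution below ``threshold``, GPD above it."""

    bulk: DistributionSpec
    threshold: float
    tail_shape: float
    tail_scale: float
    tail_fraction: float | None = None  # None => bulk-based 1 - H(u)

    def __post_init__(self) -> None:
        if self.bulk.family not in _BULK_FAMILIES:
            raise ValidationError(f"unsupported bulk family {self.bulk.family}")
        if self.tail_scale <= 0:
            raise ValidationError("tail_scale must be > 0")
        hu = float(self.bulk.cdf(self.threshold))
        if not 0.0 < hu < 1.0:
            raise ValidationError("threshold must lie strictly inside the bulk support")
        if self.tail_fraction is not None and not 0.0 < self.tail_fraction < 1.0:
            raise ValidationError("tail_fraction must lie in (0, 1)")

    # -- derived quantities ------------------------------------------------
    @property
    def bulk_weight(self) -> float:
        """P(X < u): H(u) in the bulk-based form, 1 - phi otherwise."""
        if self.tail_fraction is None:
            return float(self.bulk.cdf(self.threshold))
        return 1.0 - self.tail_fraction

    def upper_endpoint(self) -> float:
        if self.tail_shape < -XI_EPS:
            return self.threshold - self.tail_scale / self.tail_shape
        return math.inf

    # -- evaluation --------------------------------------------------------
    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        u = self.threshold
        w = self.bulk_weight
        hu = float(self.bulk.cdf(u))
        below = np.asarray(self.bulk.cdf(np.minimum(x, u)), dtype=float)
        if self.tail_fraction is not None:
            below = below / hu * w  # bulk renormalised below u in the free-phi variant
        tail = w + (1.0 - w) * _gpd_cdf(
            np.maximum(x, u), self.tail_shape, self.tail_scale, u
        )
        out = np.where(x < u, below, tail)
        return out if out.ndim else float(out)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        u = self.threshold
        w = self.bulk_weight
        hu = float(self.bulk.cdf(u))
        below = np.asarray(self.bulk.pdf(x), dtype=float)
        if self.tail_fraction is not None:
            below = below / hu * w
        tail = (1.0 - w) * _gpd_pdf(x, self.tail_shape, self.tail_scale, u)
        out = np.where(x < u, below, tail)
        return out if out.ndim else float(out)

    def quantile(self, p):
        p_arr = np.asarray(p, dtype=float)
        if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
            raise ValidationError("quantile probability must lie strictly in (0, 1)")
        u = self.threshold
        w = self.bulk_weight
        hu = float(self.bulk.cdf(u))
        pb = np.clip(p_arr, 1e-300, w)
        if self.tail_fraction is not None:
            pb = pb / w * hu
        below = self.bulk.quantile(np.minimum(pb, hu * (1 - 1e-16)))
        q_tail = (np.maximum(p_arr, w) - w) / (1.0 - w)
        tail = _gpd_ppf(np.clip(q_tail, 0.0, 1.0 - 1e-16), self.tail_shape, self.tail_scale, u)
        out = np.where(p_arr < w, below, tail)
        return out if out.ndim else float(out)

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        """Composition sampling via inverse CDF on a single uniform stream."""
        if n < 1:
            raise ValidationError("n must be >= 1")
        rng = as_rng(seed)
        return np.asarray(self.quantile(rng.uniform(size=n)), dtype=float)

    def as_dict(self) -> dict:
        return {
            "bulk": self.bulk.as_dict(),
            "threshold": self.threshold,
            "tail_shape": self.tail_shape,
            "tail_scale": self.tail_scale,
            "tail_fraction": self.tail_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvmmSpec":
        return cls(
            bulk=DistributionSpec.from_dict(d["bulk"]),
            threshold=d["threshold"],
            tail_shape=d["tail_shape"],
            tail_scale=d["tail_scale"],
            tail_fraction=d.get("tail_fraction"),
        )


@dataclass(frozen=True)
class EvmmFitResult:
    spec: EvmmSpec
    loglik: float
    n: int
    k: int
    n_exceedances: int
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
            "n_exceedances": self.n_exceedances,
            "converged": self.converged,
            "aic": self.aic,
            "bic": self.bic,
        }


# ---------------------------------------------------------------------------
# Joint likelihood machinery
# ---------------------------------------------------------------------------

def _bulk_from_theta(family: Family, theta: np.ndarray) -> DistributionSpec | None:
    """Unconstrained parameter vector -> bulk spec (None if invalid)."""
    try:
        if family is Family.LOGNORMAL:
            return DistributionSpec.lognormal(theta[0], math.exp(theta[1]))
        if family is Family.WEIBULL:
            return DistributionSpec.weibull(math.exp(theta[0]), math.exp(theta[1]))
        return DistributionSpec.gamma(math.exp(theta[0]), math.exp(theta[1]))
    except (OverflowError, ValidationError):
        return None


def _theta_from_bulk(spec: DistributionSpec) -> list[float]:
    if spec.family is Family.LOGNORMAL:
        return [spec.params[0], math.log(spec.params[1])]
    return [math.log(spec.params[0]), math.log(spec.params[1])]


def _bulk_mle(family: Family, x: np.ndarray) -> DistributionSpec:
    if family is Family.LOGNORMAL:
        return DistributionSpec.lognormal(*lognormal_mle(x))
    if family is Family.WEIBULL:
        return DistributionSpec.weibull(*weibull_mle(x))
    return DistributionSpec.gamma(*gamma_mle(x))


def _make_nll(family: Family, u: float, below: np.ndarray, exc: np.ndarray):
    """Negative joint log-likelihood closure at a fixed threshold.

    theta = (bulk unconstrained..., xi, log sigma).  Bulk density applies
    as-is below u; each exceedance contributes log(1 - H(u)) + GPD logpdf.
    Bulk terms use sufficient statistics so each evaluation is O(n_exc)
    (O(n) only for the Weibull shape term).
    """
    from scipy.special import gammainc, gammaln, ndtr

    n_b = below.size
    n_e = exc.size
    if family is Family.LOGNORMAL:
        lx = np.log(below)
        s1, s2 = float(lx.sum()), float((lx * lx).sum())
        lu = math.log(u)

        def bulk_ll(tb):
            mu, logsd = float(tb[0]), float(tb[1])
            if abs(logsd) > 50.0:
                return -np.inf, 0.0
            sd = math.exp(logsd)
            ss = s2 - 2.0 * mu * s1 + n_b * mu * mu
            ll = -s1 - n_b * (logsd + 0.5 * math.log(2 * math.pi)) - ss / (2 * sd * sd)
            return ll, float(ndtr((lu - mu) / sd))

    elif family is Family.GAMMA:
        s_logx = float(np.log(below).sum())
        s_x = float(below.sum())

        def bulk_ll(tb):
            if abs(tb[0]) > 50.0 or abs(tb[1]) > 50.0:
                return -np.inf, 0.0
            a, r = math.exp(tb[0]), math.exp(tb[1])
            ll = n_b * (a * math.log(r) - gammaln(a)) + (a - 1.0) * s_logx - r * s_x
            return float(ll), float(gammainc(a, r * u))

    else:  # weibull
        lx = np.log(below)
        s_logx = float(lx.sum())
        lu = math.log(u)

        def bulk_ll(tb):
            if abs(tb[0]) > 50.0 or abs(tb[1]) > 50.0:
                return -np.inf, 0.0
            k, llam = math.exp(tb[0]), float(tb[1])
            with np.errstate(over="ignore"):
                sxk = float(np.exp(np.clip(k * (lx - llam), -745.0, 709.0)).sum())
            ll = n_b * (tb[0] - k * llam) + (k - 1.0) * s_logx - sxk
            zk = k * (lu - llam)
            hu = -math.expm1(-math.exp(zk)) if zk < 700.0 else 1.0
            return float(ll), hu

    def nll(theta) -> float:
        ll_b, hu = bulk_ll(theta[:-2])
        if not math.isfinite(ll_b) or not 1e-12 < hu < 1.0 - 1e-12:
            return 1e12
        xi, logsig = float(theta[-2]), float(theta[-1])
        # keep the tail index in a physically plausible band; unbounded xi is
        # a known likelihood degeneracy with very few exceedances
        if abs(logsig) > 50.0 or not -5.0 < xi < 10.0:
            return 1e12
        sigma = math.exp(logsig)
        z = exc / sigma
        if abs(xi) < XI_EPS:
            tail = -float(z.sum()) - n_e * logsig
        else:
            t = 1.0 + xi * z
            if np.any(t <= 0.0):
                return 1e12
            tail = (-1.0 / xi - 1.0) * float(np.log(t).sum()) - n_e * logsig
        total = ll_b + n_e * math.log1p(-hu) + tail
        return -total if math.isfinite(total) else 1e12

    return nll


def _fit_at_threshold(
    x: np.ndarray,
    family: Family,
    u: float,
    theta0: np.ndarray,
    maxiter: int,
) -> tuple[float, np.ndarray] | None:
    below = x[x < u]
    exc = x[x >= u] - u
    if exc.size < 2 or below.size < 1:
        return None
    res = optimize.minimize(
        _make_nll(family, u, below, exc), x0=theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": maxiter},
    )
    if not math.isfinite(res.fun) or res.fun >= 1e11:
        return None
    return float(res.fun), np.asarray(res.x, dtype=float)


def evmm_fit(
    data,
    bulk_family: Family | str,
    *,
    threshold_grid: tuple[float, ...] | None = None,
    min_exceedances: int = 2,
    refine: bool = True,
    maxiter: int = 400,
) -> EvmmFitResult:
    """Joint MLE of (bulk params, u, xi, sigma) by threshold profiling.

    ``threshold_grid`` lists candidate thresholds as percentile points of the
    sample (default P50..P95 in steps of 2.5).  Candidates leaving fewer than
    ``min_exceedances`` points above them are skipped.  The best grid point is
    then refined by bounded local optimisation of ``u`` between its grid
    neighbours (``refine=True``).
    """
    family = Family(bulk_family)
    if family not in _BULK_FAMILIES:
        raise ValidationError(f"unsupported bulk family {family}")
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValidationError("need at least 10 positive observations")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValidationError("data must be finite and strictly positive")

    grid = DEFAULT_THRESHOLD_GRID if threshold_grid is None else tuple(threshold_grid)
    bulk0 = _bulk_mle(family, x)
    theta_bulk0 = _theta_from_bulk(bulk0)

    best: tuple[float, float, np.ndarray] | None = None  # (nll, u, theta)
    candidates: list[float] = []
    for q in grid:
        u = float(np.quantile(x, q / 100.0))
        exc = x[x >= u]
        if exc.size < min_exceedances or not np.any(x < u):
            continue
        candidates.append(u)
        sigma0 = float(np.std(exc - u)) or float(np.mean(exc - u)) or 1.0
        theta0 = np.array([*theta_bulk0, 0.1, math.log(sigma0)])
        fit = _fit_at_threshold(x, family, u, theta0, maxiter)
        if fit is None:
            continue
        nll, theta = fit
        if best is None or nll < best[0]:
            best = (nll, u, theta)
    if best is None:
        raise FitError("no candidate threshold admits the minimum number of exceedances")

    nll_best, u_best, theta_best = best
    converged = True
    if refine and len(candidates) > 1:
        cand = np.sort(np.asarray(candidates))
        i = int(np.argmin(np.abs(cand - u_best)))
        lo = cand[i - 1] if i > 0 else cand[i]
        hi = cand[i + 1] if i + 1 < cand.size else cand[i]
        if hi > lo:
            def profile(u: float) -> float:
                fit = _fit_at_threshold(x, family, float(u), theta_best, maxiter // 2)
                return fit[0] if fit is not None else 1e12

            res = optimize.minimize_scalar(
                profile, bounds=(lo, hi), method="bounded",
                options={"xatol": max((hi - lo) * 1e-3, 1e-10), "maxiter": 25},
            )
            if math.isfinite(res.fun) and res.fun < nll_best:
                fit = _fit_at_threshold(x, family, float(res.x), theta_best, maxiter)
                if fit is not None:
                    nll_best, u_best, theta_best = fit[0], float(res.x), fit[1]

    # final polish at the chosen threshold
    fit = _fit_at_threshold(x, family, u_best, theta_best, maxiter * 2)
    if fit is not None and fit[0] <= nll_best:
        nll_best, theta_best = fit
    bulk = _bulk_from_theta(family, theta_best[:-2])
    if bulk is None:
        raise FitError("optimizer returned invalid bulk parameters")
    spec = EvmmSpec(
        bulk=bulk,
        threshold=u_best,
        tail_shape=float(theta_best[-2]),
        tail_scale=float(math.exp(theta_best[-1])),
    )
    n_exc = int(np.sum(x >= u_best))
    k = bulk.k + 3  # bulk params plus (u, xi, sigma)
    loglik = -nll_best
    if not math.isfinite(loglik):
        converged = False
    return EvmmFitResult(
        spec=spec, loglik=loglik, n=int(x.size), k=k,
        n_exceedances=n_exc, converged=converged,
    )
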