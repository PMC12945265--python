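"""Finite mixtures of positive right-skewed components, fitted by EM.

Components all share one family (lognormal, Weibull or gamma).  The M-step
uses closed-form weighted MLE for lognormal components and 1-D numerical
profile equations for the Weibull/gamma shape.  Label switching is resolved
by sorting components by their means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._utils import FitError, ValidationError, as_rng
from .distributions import (
    DistributionSpec,
    Family,
    gamma_mle,
    lognormal_mle,
    weibull_mle,
)

__all__ = ["MixtureSpec", "MixtureFitResult", "mixture_fit_em"]

_COMPONENT_FAMILIES = (Family.LOGNORMAL, Family.WEIBULL, Family.GAMMA)


@dataclass(frozen=True)
class MixtureSpec:
    """Weighted sum of same-family components, ordered by increasing mean."""

    weights: tuple[float, ...]
    components: tuple[DistributionSpec, ...]

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        comps = tuple(self.components)
        if len(w) != len(comps) or not comps:
            raise ValidationError("weights and components must align and be non-empty")
        if any(v < 0 for v in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValidationError("weights must be nonnegative and sum to 1")
        fams = {c.family for c in comps}
        if len(fams) != 1 or fams.pop() not in _COMPONENT_FAMILIES:
            raise ValidationError("components must share one supported family")
        order = np.argsort([c.mean() for c in comps], kind="stable")
        object.__setattr__(self, "weights", tuple(w[i] for i in order))
        object.__setattr__(self, "components", tuple(comps[i] for i in order))

    @property
    def g(self) -> int:
        return len(self.components)

    @property
    def family(self) -> Family:
        return self.components[0].family

    @property
    def k(self) -> int:
        return sum(c.k for c in self.components) + (self.g - 1)

    def mean(self) -> float:
        return float(sum(w * c.mean() for w, c in zip(self.weights, self.components)))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = sum(w * np.asarray(c.pdf(x)) for w, c in zip(self.weights, self.components))
        out = np.asarray(out, dtype=float)
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = sum(w * np.asarray(c.cdf(x)) for w, c in zip(self.weights, self.components))
        out = np.asarray(out, dtype=float)
        return out if out.ndim else float(out)

    def quantile(self, p):
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
            raise ValidationError("quantile probability must lie strictly in (0, 1)")
        out = np.empty_like(p_arr)
        active = [(w, c) for w, c in zip(self.weights, self.components) if w > 0]
        for i, pi in enumerate(p_arr):
            brackets = [c.quantile(pi) for _, c in active]
            lo, hi = min(brackets), max(brackets)
            if hi - lo < 1e-300:
                out[i] = lo
                continue
            out[i] = optimize.brentq(
                lambda x: self.cdf(x) - pi, lo, hi, xtol=1e-12, rtol=1e-12
            )
        return out if np.ndim(p) else float(out[0])

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        if n < 1:
            raise ValidationError("n must be >= 1")
        rng = as_rng(seed)
        labels = rng.choice(self.g, size=n, p=np.asarray(self.weights))
        out = np.empty(n, dtype=float)
        for j, comp in enumerate(self.components):
            mask = labels == j
            cnt = int(mask.sum())
            if cnt:
                out[mask] = comp.sample(cnt, rng)
        return out

    def as_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "components": [c.as_dict() for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(
            weights=tuple(d["weights"]),
            components=tuple(DistributionSpec.from_dict(c) for c in d["components"]),
        )


@dataclass(frozen=True)
class MixtureFitResult:
    spec: MixtureSpec
    loglik: float
    n: int
    k: int
    n_iter: int
    converged: bool
    loglik_trace: tuple[float, ...] = ()

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
            "n_iter": self.n_iter,
            "converged": self.converged,
            "aic": self.aic,
            "bic": self.bic,
        }


# ---------------------------------------------------------------------------
# EM internals
# ---------------------------------------------------------------------------

_WEIGHTED_MLE = {
    Family.LOGNORMAL: lognormal_mle,
    Family.GAMMA: gamma_mle,
    Family.WEIBULL: weibull_mle,
}

_LOG_2PI = math.log(2.0 * math.pi)


def _logpdf_cols(family: Family, x: np.ndarray, logx: np.ndarray, params: list) -> np.ndarray:
    """(n, g) log-density matrix without scipy frozen-dist overhead."""
    from scipy.special import gammaln

    cols = []
    for p in params:
        if family is Family.LOGNORMAL:
            mu, sd = p
            cols.append(-logx - math.log(sd) - 0.5 * _LOG_2PI - (logx - mu) ** 2 / (2 * sd * sd))
        elif family is Family.GAMMA:
            a, r = p
            cols.append(a * math.log(r) - gammaln(a) + (a - 1.0) * logx - r * x)
        else:  # weibull
            k, lam = p
            llam = math.log(lam)
            cols.append(
                math.log(k) - k * llam + (k - 1.0) * logx
                - np.exp(np.clip(k * (logx - llam), -745.0, 709.0))
            )
    return np.column_stack(cols)


def _check_params(family: Family, params: list) -> None:
    for p in params:
        if not all(map(math.isfinite, p)):
            raise FitError("non-finite component parameters")
        if family is Family.LOGNORMAL and p[1] < 1e-8:
            raise FitError("lognormal component variance collapse")
        if family is not Family.LOGNORMAL and (p[0] <= 0 or p[1] <= 0):
            raise FitError("non-positive component parameters")


def _split_init(x: np.ndarray, family: Family, q: float) -> tuple[np.ndarray, list]:
    """Initialise by fitting each side of the q-quantile split."""
    cut = np.quantile(x, q)
    lo = x[x <= cut]
    hi = x[x > cut]
    if lo.size < 3 or hi.size < 3:
        raise FitError("split too unbalanced to initialise")
    mle = _WEIGHTED_MLE[family]
    return np.array([q, 1.0 - q]), [mle(lo), mle(hi)]


def _em_once(
    x: np.ndarray,
    family: Family,
    pi: np.ndarray,
    params: list,
    *,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list, float, int, bool, list[float]]:
    n = x.size
    logx = np.log(x)
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    mle = _WEIGHTED_MLE[family]
    for it in range(1, max_iter + 1):
        logf = _logpdf_cols(family, x, logx, params) + np.log(pi)[None, :]
        m = logf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logf - m).sum(axis=1))
        ll = float(lse.sum())
        if not math.isfinite(ll):
            raise FitError("log-likelihood diverged")
        trace.append(ll)
        resp = np.exp(logf - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-6 * n):
            raise FitError("degenerate component weight")
        pi = nk / n
        params = [mle(x, resp[:, j]) for j in range(len(params))]
        _check_params(family, params)
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            break
        ll_prev = ll
    logf = _logpdf_cols(family, x, logx, params) + np.log(pi)[None, :]
    m = logf.max(axis=1, keepdims=True)
    ll = float((m[:, 0] + np.log(np.exp(logf - m).sum(axis=1))).sum())
    trace.append(ll)
    return pi, params, ll, it, converged, trace


def mixture_fit_em(
    data,
    family: Family | str,
    g: int = 2,
    *,
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFitResult:
    """Best-of-restarts EM fit of a g-component same-family mixture.

    The first start splits the data at the median and fits each half by MLE
    with equal mixing weights; further restarts perturb the split point to a
    random quantile in (0.2, 0.8).
    """
    family = Family(family)
    if family not in _COMPONENT_FAMILIES:
        raise ValidationError(f"unsupported mixture family {family}")
    if g < 1:
        raise ValidationError("g must be >= 1")
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size < 5 * g:
        raise ValidationError(f"need at least {5 * g} observations")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValidationError("data must be finite and strictly positive")

    if g == 1:
        spec = MixtureSpec((1.0,), (DistributionSpec(family, _WEIGHTED_MLE[family](x)),))
        ll = float(np.sum(spec.components[0].logpdf(x)))
        return MixtureFitResult(spec, ll, int(x.size), spec.k, 1, True, (ll,))
    if g != 2:
        raise ValidationError("only g in {1, 2} is supported")

    rng = as_rng(seed)
    best: MixtureFitResult | None = None
    n_failed = 0
    for r in range(n_restarts):
        q = 0.5 if r == 0 else float(rng.uniform(0.2, 0.8))
        try:
            pi0, params0 = _split_init(x, family, q)
            pi0 = np.array([0.5, 0.5]) if r == 0 else pi0
            pi, params, ll, it, conv, trace = _em_once(
                x, family, pi0, params0, tol=tol, max_iter=max_iter
            )
            spec = MixtureSpec(
                tuple(pi), tuple(DistributionSpec(family, p) for p in params)
            )
        except (FitError, ValidationError, FloatingPointError):
            n_failed += 1
            continue
        result = MixtureFitResult(
            spec=spec, loglik=ll, n=int(x.size), k=spec.k,
            n_iter=it, converged=conv, loglik_trace=tuple(trace),
        )
        if best is None or result.loglik > best.loglik:
            best = result
    if best is None:
        raise FitError(f"all {n_restarts} EM restarts degenerated")
    return best
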