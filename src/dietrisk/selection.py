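"""Three-stage model evaluation for positive concentration data.

Stage 1 screens candidates with Kolmogorov-Smirnov and Anderson-Darling
tests whose p-values come from a parametric bootstrap (parameters are
estimated, so textbook tables would be invalid).  Stage 2 ranks survivors by
information criteria.  Stage 3 scores top-ranked survivors by Monte Carlo
percentile deviations from the observed data, prioritising the 99.9th
percentile, and names the winner.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import FitError, ValidationError, as_rng
from .distributions import Family, FitResult, fit_mle
from .evmm import EvmmFitResult, evmm_fit
from .mixture import MixtureFitResult, mixture_fit_em

__all__ = [
    "GofResult",
    "CandidateResult",
    "SelectionReport",
    "CANDIDATE_LABELS",
    "fit_candidate",
    "ks_statistic",
    "ad_statistic",
    "gof_test",
    "relative_difference",
    "stage3_deviation",
    "select_model",
]

#: every candidate family label the selection protocol understands
CANDIDATE_LABELS: tuple[str, ...] = (
    "lognormal", "weibull", "gamma", "exponential",
    "lognormal-gpd", "weibull-gpd", "gamma-gpd",
    "2-lognormal", "2-weibull", "2-gamma",
)

AnyFit = FitResult | EvmmFitResult | MixtureFitResult


def fit_candidate(
    data,
    label: str,
    *,
    seed: int | np.random.Generator | None = None,
    fast: bool = False,
    ref: AnyFit | None = None,
) -> AnyFit:
    """Fit one candidate family by its label.

    ``fast=True`` is used inside bootstrap loops: spliced-tail refits keep the
    threshold at the reference fit's percentile rank (no profile search) and
    mixtures use 2 EM restarts instead of 10.
    """
    if label not in CANDIDATE_LABELS:
        raise ValidationError(f"unknown candidate {label!r}; known: {CANDIDATE_LABELS}")
    if label.endswith("-gpd"):
        bulk = Family(label[:-4])
        if fast and isinstance(ref, EvmmFitResult):
            rank = 100.0 * float(np.mean(np.asarray(ref.spec.cdf(ref.spec.threshold))))
            rank = min(max(rank, 50.0), 95.0)
            return evmm_fit(data, bulk, threshold_grid=(rank,), refine=False)
        if fast:
            return evmm_fit(data, bulk, threshold_grid=(70.0, 80.0, 90.0), refine=False)
        return evmm_fit(data, bulk)
    if label.startswith("2-"):
        if fast:
            return mixture_fit_em(
                data, Family(label[2:]), g=2, n_restarts=2, seed=seed,
                tol=1e-6, max_iter=300,
            )
        return mixture_fit_em(data, Family(label[2:]), g=2, n_restarts=10, seed=seed)
    return fit_mle(data, Family(label))


def candidate_label(fitted: AnyFit) -> str:
    if isinstance(fitted, EvmmFitResult):
        return f"{fitted.spec.bulk.family.value}-gpd"
    if isinstance(fitted, MixtureFitResult):
        return f"{fitted.spec.g}-{fitted.spec.family.value}"
    return fitted.spec.family.value


# ---------------------------------------------------------------------------
# Test statistics
# ---------------------------------------------------------------------------

def ks_statistic(data, cdf) -> float:
    """sup |ECDF - F| for a fully specified CDF."""
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    z = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - z, z - (i - 1) / n)))


def ad_statistic(data, cdf) -> float:
    """Anderson-Darling A^2 via the standard sorted-sample sum."""
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    z = np.clip(np.asarray(cdf(x), dtype=float), 1e-300, 1.0 - 1e-15)
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    return float(-n - s / n)


@dataclass(frozen=True)
class GofResult:
    ks_p: float
    ad_p: float
    B: int
    ks_stat: float = math.nan
    ad_stat: float = math.nan
    n_failed: int = 0
    flagged: bool = False

    def as_dict(self) -> dict:
        return {
            "ks_p": self.ks_p, "ad_p": self.ad_p, "B": self.B,
            "ks_stat": self.ks_stat, "ad_stat": self.ad_stat,
            "n_failed": self.n_failed, "flagged": self.flagged,
        }


def gof_test(
    data,
    fitted: AnyFit,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    fast_refit: bool = True,
) -> GofResult:
    """Parametric-bootstrap KS and AD p-values for a fitted model.

    Simulates B datasets of the observed size from the fitted model, refits
    the same family to each, and recomputes both statistics; the p-value is
    ``(1 + #{stat_b >= stat_obs}) / (B + 1)``.  Refit failures are dropped
    and counted; more than 20% failures flags the result.
    """
    x = np.asarray(data, dtype=float)
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = as_rng(seed)
    label = candidate_label(fitted)
    ks_obs = ks_statistic(x, fitted.spec.cdf)
    ad_obs = ad_statistic(x, fitted.spec.cdf)
    ks_ge = ad_ge = 0
    n_ok = n_failed = 0
    for _ in range(B):
        sim = fitted.spec.sample(x.size, rng)
        try:
            refit = fit_candidate(sim, label, seed=rng, fast=fast_refit, ref=fitted)
        except (FitError, ValidationError):
            n_failed += 1
            continue
        n_ok += 1
        if ks_statistic(sim, refit.spec.cdf) >= ks_obs:
            ks_ge += 1
        if ad_statistic(sim, refit.spec.cdf) >= ad_obs:
            ad_ge += 1
    if n_ok == 0:
        raise FitError("all bootstrap refits failed")
    return GofResult(
        ks_p=(1 + ks_ge) / (n_ok + 1),
        ad_p=(1 + ad_ge) / (n_ok + 1),
        B=n_ok,
        ks_stat=ks_obs,
        ad_stat=ad_obs,
        n_failed=n_failed,
        flagged=n_failed > 0.2 * B,
    )


# ---------------------------------------------------------------------------
# Stage 3: Monte Carlo percentile deviations
# ---------------------------------------------------------------------------

def relative_difference(estimated: float, original: float) -> float:
    """100 * |estimated - original| / original, in percent."""
    if original <= 0:
        raise ValidationError("original value must be > 0")
    return 100.0 * abs(float(estimated) - float(original)) / float(original)


def stage3_deviation(
    fitted: AnyFit,
    data,
    n_sim: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Relative % deviations of simulated mean/P95/P99.9 from the observed ones."""
    x = np.asarray(data, dtype=float)
    draws = fitted.spec.sample(n_sim, as_rng(seed))
    out = {}
    for name, emp, sim in (
        ("mean", float(np.mean(x)), float(np.mean(draws))),
        ("p95", float(np.percentile(x, 95)), float(np.percentile(draws, 95))),
        ("p99_9", float(np.percentile(x, 99.9)), float(np.percentile(draws, 99.9))),
    ):
        out[name] = relative_difference(sim, emp)
    return out


# ---------------------------------------------------------------------------
# Ranked report
# ---------------------------------------------------------------------------

@dataclass
class CandidateResult:
    label: str
    fit: AnyFit | None
    gof: GofResult | None
    stage1_pass: bool
    rank: int | None = None
    deviations: dict[str, float] | None = None
    error: str | None = None

    @property
    def aic(self) -> float | None:
        return self.fit.aic if self.fit is not None else None

    @property
    def bic(self) -> float | None:
        return self.fit.bic if self.fit is not None else None


@dataclass
class SelectionReport:
    candidates: list[CandidateResult]
    winner: str | None
    status: str  # "ok" | "no_adequate_model"
    alpha: float
    tie: bool = False

    def as_dict(self) -> dict:
        return {
            "status": self.status,
            "winner": self.winner,
            "alpha": self.alpha,
            "tie": self.tie,
            "candidates": [
                {
                    "label": c.label,
                    "error": c.error,
                    "stage1_pass": c.stage1_pass,
                    "rank": c.rank,
                    "aic": c.aic,
                    "bic": c.bic,
                    "gof": c.gof.as_dict() if c.gof else None,
                    "deviations": c.deviations,
                    "fit": c.fit.as_dict() if c.fit else None,
                }
                for c in self.candidates
            ],
        }

    def to_json(self, path=None, **extra) -> str:
        payload = {**self.as_dict(), **extra}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        """Human-readable table mirroring a GOF/IC comparison layout."""
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "model": c.label,
                    "KS": c.gof.ks_p if c.gof else None,
                    "AD": c.gof.ad_p if c.gof else None,
                    "AIC": c.aic,
                    "BIC": c.bic,
                    "stage1_pass": c.stage1_pass,
                    "rank": c.rank,
                    "dev_mean_%": (c.deviations or {}).get("mean"),
                    "dev_p95_%": (c.deviations or {}).get("p95"),
                    "dev_p99.9_%": (c.deviations or {}).get("p99_9"),
                }
            )
        return pd.DataFrame(rows)

    def winning_fit(self) -> AnyFit:
        if self.winner is None:
            raise ValidationError("no adequate model was selected")
        for c in self.candidates:
            if c.label == self.winner:
                return c.fit
        raise AssertionError("winner not among candidates")


def select_model(
    data,
    candidates: list[str] | tuple[str, ...],
    *,
    alpha: float = 0.05,
    B: int = 1000,
    n_sim: int = 10_000,
    seed: int | np.random.Generator | None = None,
    shortlist_k: int = 3,
    ic: str = "bic",
    aggregation: str = "lexicographic",
    fast_refit: bool = True,
) -> SelectionReport:
    """Run the full three-stage protocol and return a ranked report.

    Stage 2 ranks stage-1 survivors by ``ic`` (default BIC, AIC tie-break)
    and keeps the top ``shortlist_k``.  Stage 3 scores the shortlist by
    simulated percentile deviations; by default the winner minimises the
    P99.9 deviation (ties broken by mean, then P95); ``aggregation="mean"``
    instead averages the three deviations.
    """
    if ic not in ("bic", "aic"):
        raise ValidationError("ic must be 'bic' or 'aic'")
    if aggregation not in ("lexicographic", "mean"):
        raise ValidationError("aggregation must be 'lexicographic' or 'mean'")
    x = np.asarray(data, dtype=float)
    # an int seed spawns one named substream per candidate, so each
    # candidate's p-values are independent of which others are in the list
    if isinstance(seed, (int, np.integer)):
        from ._utils import spawn_seed

        master = int(seed)
        stream = lambda name: as_rng(spawn_seed(master, name))  # noqa: E731
    else:
        rng = as_rng(seed)
        stream = lambda name: rng  # noqa: E731
    results: list[CandidateResult] = []
    for label in candidates:
        try:
            sub = stream(f"cand:{label}")
            fit = fit_candidate(x, label, seed=sub)
            gof = gof_test(x, fit, B=B, seed=sub, fast_refit=fast_refit)
        except (FitError, ValidationError) as exc:
            results.append(CandidateResult(label, None, None, False, error=str(exc)))
            continue
        ok = gof.ks_p >= alpha and gof.ad_p >= alpha
        results.append(CandidateResult(label, fit, gof, ok))

    survivors = [c for c in results if c.stage1_pass]
    survivors.sort(key=lambda c: (getattr(c.fit, ic), c.fit.aic))
    for i, c in enumerate(survivors):
        c.rank = i + 1
    shortlist = survivors[: max(shortlist_k, 1)]
    winner = None
    tie = False
    if shortlist:
        keys = []
        for c in shortlist:
            c.deviations = stage3_deviation(
                c.fit, x, n_sim=n_sim, seed=stream(f"stage3:{c.label}")
            )
            d = c.deviations
            if aggregation == "lexicographic":
                keys.append((d["p99_9"], d["mean"], d["p95"]))
            else:
                keys.append(((d["p99_9"] + d["mean"] + d["p95"]) / 3.0,))
        best = min(range(len(shortlist)), key=keys.__getitem__)
        tie = sum(1 for k in keys if k == keys[best]) > 1
        winner = shortlist[best].label
    status = "ok" if winner is not None else "no_adequate_model"
    return SelectionReport(
        candidates=results, winner=winner, status=status, alpha=alpha, tie=tie
    )
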