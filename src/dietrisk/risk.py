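"""Risk characterization: hazard quotients, cumulative hazard index, and
bootstrap confidence intervals for exposure/risk percentiles.

HQ = EDI / TDI per analyte.  Co-exposure is combined with relative potency
factors against a group TDI expressed in DEHP equivalents::

    HI = (EDI_DEHP * RPF_DEHP + EDI_DBP * RPF_DBP) / group_TDI

with defaults TDI(DEHP)=50, TDI(DBP)=10 ug/(kg bw)/day, RPF 1 and 5, and
group TDI 50.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import FitError, ValidationError, as_rng, round_half_up
from .exposure import (
    SUMMARY_POINTS,
    ConcentrationDataset,
    DemographicGroup,
    simulate_exposure,
    summarize,
)
from .selection import fit_candidate

__all__ = [
    "ToxParams",
    "DEFAULT_TOX",
    "hazard_quotient",
    "hazard_index",
    "RiskReport",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class ToxParams:
    analyte: str
    tdi: float
    rpf: float = 1.0
    group_tdi: float = 50.0

    def __post_init__(self) -> None:
        if self.tdi <= 0 or self.rpf <= 0 or self.group_tdi <= 0:
            raise ValidationError("tdi, rpf and group_tdi must be > 0")


#: EFSA-based defaults for the two analytes of interest
DEFAULT_TOX: dict[str, ToxParams] = {
    "DEHP": ToxParams("DEHP", tdi=50.0, rpf=1.0, group_tdi=50.0),
    "DBP": ToxParams("DBP", tdi=10.0, rpf=5.0, group_tdi=50.0),
}


def hazard_quotient(edi, tdi: float):
    """HQ = EDI / TDI, applied pointwise (scalar or array)."""
    if tdi <= 0:
        raise ValidationError("TDI must be > 0")
    edi_arr = np.asarray(edi, dtype=float)
    if np.any(edi_arr < 0):
        raise ValidationError("EDI must be nonnegative")
    out = edi_arr / tdi
    return out if out.ndim else float(out)


def hazard_index(edi_dehp, edi_dbp, tox: dict[str, ToxParams] | None = None):
    """RPF-weighted cumulative hazard index at matched percentiles.

    Both analytes are required; a single-analyte HI would silently understate
    the co-exposure risk.
    """
    tox = DEFAULT_TOX if tox is None else tox
    try:
        dehp, dbp = tox["DEHP"], tox["DBP"]
    except KeyError as exc:
        raise ValidationError(f"missing tox params for analyte {exc}") from exc
    if edi_dehp is None or edi_dbp is None:
        raise ValidationError("HI requires EDI for both DEHP and DBP")
    if dehp.group_tdi != dbp.group_tdi:
        raise ValidationError("analytes must share one group TDI")
    a = np.asarray(edi_dehp, dtype=float)
    b = np.asarray(edi_dbp, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("EDI must be nonnegative")
    out = (a * dehp.rpf + b * dbp.rpf) / dehp.group_tdi
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class RiskReport:
    """Per-group EDI/HQ/HI summaries, optionally with bootstrap CIs.

    ``edi`` maps analyte -> group -> {point -> value}; ``ci`` (if present)
    maps the same keys to (lo, hi) pairs.
    """

    edi: dict[str, dict[str, dict[str, float]]]
    tox: dict[str, ToxParams]
    ci: dict[str, dict[str, dict[str, tuple[float, float]]]] | None = None
    ndigits: int = 3

    def hq(self, analyte: str, group: str) -> dict[str, float]:
        tdi = self.tox[analyte].tdi
        return {k: hazard_quotient(v, tdi) for k, v in self.edi[analyte][group].items()}

    def hi(self, group: str) -> dict[str, float]:
        return {
            k: hazard_index(
                self.edi["DEHP"][group][k], self.edi["DBP"][group][k], self.tox
            )
            for k in SUMMARY_POINTS
        }

    def to_frame(self) -> pd.DataFrame:
        """EDI + HQ table, one row per analyte x group (report rounding)."""
        rows = []
        for analyte, groups in self.edi.items():
            for group, summ in groups.items():
                row = {"analyte": analyte, "group": group}
                for k in SUMMARY_POINTS:
                    row[f"edi_{k}"] = round_half_up(summ[k], self.ndigits)
                    if self.ci and group in self.ci.get(analyte, {}):
                        lo, hi = self.ci[analyte][group][k]
                        row[f"edi_{k}_ci"] = (
                            f"({round_half_up(lo, self.ndigits)}, "
                            f"{round_half_up(hi, self.ndigits)})"
                        )
                hq = self.hq(analyte, group)
                row["hq_mean"] = round_half_up(hq["mean"], self.ndigits)
                row["hq_p95"] = round_half_up(hq["p95"], self.ndigits)
                rows.append(row)
        return pd.DataFrame(rows)

    def hi_frame(self) -> pd.DataFrame:
        """Cumulative HI table, one row per group (report rounding)."""
        rows = []
        for group in self.edi["DEHP"]:
            row = {"group": group}
            for k, v in self.hi(group).items():
                row[f"hi_{k}"] = round_half_up(v, self.ndigits)
            rows.append(row)
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        out = {
            "edi": self.edi,
            "hq": {a: {g: self.hq(a, g) for g in gs} for a, gs in self.edi.items()},
            "tox": {a: vars(t).copy() for a, t in self.tox.items()},
        }
        if all(a in self.edi for a in ("DEHP", "DBP")):
            out["hi"] = {g: self.hi(g) for g in self.edi["DEHP"]}
        if self.ci is not None:
            out["ci"] = self.ci
        return out

    def to_json(self, path=None, **extra) -> str:
        text = json.dumps({**self.as_dict(), **extra}, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Bootstrap uncertainty
# ---------------------------------------------------------------------------

def bootstrap_ci(
    dataset: ConcentrationDataset,
    group: DemographicGroup,
    winner_label: str,
    *,
    B: int = 100,
    n_sim: int = 10_000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
    mode: str = "data",
) -> dict:
    """Percentile-bootstrap CIs for exposure summaries of one analyte/group.

    ``mode="data"`` (default) resamples the concentration rows with
    replacement, preserving each row's detect/non-detect status, recomputes
    the detection rate, refits the selected model family on the resampled
    positives and reruns the Monte Carlo exposure simulation with a fresh
    sub-seed.  The model family itself is fixed — only parameter and sampling
    uncertainty is propagated.  ``mode="edi"`` is a cheaper variant that only
    resamples the simulated EDI vector.

    Returns a dict with per-summary-point CIs, the positive-model mean CI,
    and replicate failure counts.
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    if mode not in ("data", "edi"):
        raise ValidationError("mode must be 'data' or 'edi'")
    rng = as_rng(seed)
    alpha = (1.0 - level) / 2.0

    if mode == "edi":
        base = simulate_exposure(
            fit_candidate(dataset.positives, winner_label, seed=rng, fast=True).spec,
            dataset.detection_rate, dataset.lod, group, dataset.analyte,
            n_sim=n_sim, seed=rng,
        )
        reps = []
        for _ in range(B):
            idx = rng.integers(0, base.n_sim, size=base.n_sim)
            reps.append(summarize(base.draws[idx]))
        return _collect(reps, [], B, alpha)

    reps = []
    conc_means = []
    n_failed = 0
    for _ in range(B):
        boot = dataset.resample(rng)
        try:
            fit = fit_candidate(boot.positives, winner_label, seed=rng, fast=True)
        except (FitError, ValidationError):
            n_failed += 1
            continue
        expo = simulate_exposure(
            fit.spec, boot.detection_rate, boot.lod, group, boot.analyte,
            n_sim=n_sim, seed=rng,
        )
        reps.append(expo.summary())
        conc_means.append(float(np.mean(boot.positives)))
    if not reps:
        raise FitError("all bootstrap replicates failed to refit")
    return _collect(reps, conc_means, B, alpha, n_failed=n_failed)


def _collect(reps, conc_means, B, alpha, n_failed: int = 0) -> dict:
    out: dict = {"B": len(reps), "n_failed": n_failed, "flagged": n_failed > 0.2 * B}
    ci = {}
    for k in SUMMARY_POINTS:
        vals = np.array([r[k] for r in reps])
        ci[k] = (
            float(np.percentile(vals, 100 * alpha)),
            float(np.percentile(vals, 100 * (1 - alpha))),
        )
    out["edi_ci"] = ci
    if conc_means:
        cm = np.asarray(conc_means)
        out["conc_mean_ci"] = (
            float(np.percentile(cm, 100 * alpha)),
            float(np.percentile(cm, 100 * (1 - alpha))),
        )
    return out
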