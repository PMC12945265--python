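"""Zero-inflated concentration simulation, consumption models, and EDI.

Concentration draws combine a Bernoulli detection indicator with the
selected positive-concentration model; non-detects are imputed uniformly on
(0, LOD).  Daily consumption is lognormal per demographic group, optionally
calibrated from published percentile targets.  The estimated daily intake is
``EDI = consumption (g/day) * concentration (mg/kg) / body weight (kg)`` in
ug/(kg bw)/day (mg/kg of food read as ug/g, so no extra unit factor).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ValidationError, as_rng

__all__ = [
    "ConcentrationDataset",
    "ConsumptionModel",
    "DemographicGroup",
    "ExposureDistribution",
    "SUMMARY_POINTS",
    "summarize",
    "simulate_concentration",
    "simulate_exposure",
    "consumption_from_percentiles",
    "compute_edi",
    "read_concentration_csv",
    "read_demographics",
]

#: reporting points for exposure summaries
SUMMARY_POINTS: tuple[str, ...] = ("mean", "p50", "p75", "p95", "p99_9")
_PCTS = {"p50": 50.0, "p75": 75.0, "p95": 95.0, "p99_9": 99.9}


def summarize(draws: np.ndarray) -> dict[str, float]:
    out = {"mean": float(np.mean(draws))}
    for name, q in _PCTS.items():
        out[name] = float(np.percentile(draws, q))
    return out


# ---------------------------------------------------------------------------
# Concentration data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationDataset:
    """Per-sample censored measurements for one analyte.

    ``values`` holds the measured concentration (mg/kg) where ``detected`` is
    True and NaN otherwise.  Detected values may legitimately sit below the
    LOD-LOQ band; they are stored as given.
    """

    analyte: str
    values: np.ndarray
    detected: np.ndarray
    lod: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        detected = np.asarray(self.detected, dtype=bool)
        if values.shape != detected.shape or values.ndim != 1 or values.size == 0:
            raise ValidationError("values/detected must be aligned non-empty vectors")
        if self.lod <= 0:
            raise ValidationError("LOD must be > 0")
        if np.any(detected & ~np.isfinite(values)):
            raise ValidationError("detected rows must carry a finite value")
        if np.any(detected & (values <= 0)):
            raise ValidationError("detected concentrations must be > 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "detected", detected)

    @property
    def n_total(self) -> int:
        return int(self.values.size)

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_total

    @property
    def positives(self) -> np.ndarray:
        return self.values[self.detected]

    def resample(self, rng: np.random.Generator) -> "ConcentrationDataset":
        """Row bootstrap preserving each row's detect/non-detect status."""
        idx = rng.integers(0, self.n_total, size=self.n_total)
        return ConcentrationDataset(
            analyte=self.analyte,
            values=self.values[idx],
            detected=self.detected[idx],
            lod=self.lod,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [f"S{i + 1:04d}" for i in range(self.n_total)],
                "analyte": self.analyte,
                "value": ["" if not d else v for v, d in zip(self.values, self.detected)],
                "detected": self.detected.astype(int),
                "lod": self.lod,
            }
        )


def read_concentration_csv(path, analyte: str | None = None) -> dict[str, ConcentrationDataset]:
    """Read a concentration table (sample_id, analyte, value, detected, lod).

    The ``value`` column may be empty for non-detected rows.  Returns one
    dataset per analyte (optionally restricted to one analyte name).
    """
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "analyte", "value", "detected", "lod"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"concentration CSV missing columns: {sorted(missing)}")
    out: dict[str, ConcentrationDataset] = {}
    for name, grp in df.groupby("analyte", sort=True):
        if analyte is not None and name != analyte:
            continue
        lods = grp["lod"].astype(float).unique()
        if lods.size != 1:
            raise ValidationError(f"analyte {name!r} has inconsistent LODs: {lods}")
        detected = grp["detected"].astype(int).to_numpy().astype(bool)
        values = pd.to_numeric(grp["value"], errors="coerce").to_numpy(dtype=float)
        values = np.where(detected, values, np.nan)
        out[str(name)] = ConcentrationDataset(
            analyte=str(name), values=values, detected=detected, lod=float(lods[0])
        )
    if analyte is not None and analyte not in out:
        raise ValidationError(f"analyte {analyte!r} not found in {path}")
    return out


# ---------------------------------------------------------------------------
# Consumption
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsumptionModel:
    """Lognormal daily intake (g/day), optionally truncated by rejection."""

    log_mean: float
    log_sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValidationError("log_sd must be > 0")
        if (self.lower is None) != (self.upper is None):
            raise ValidationError("set both truncation bounds or neither")
        if self.lower is not None:
            if self.lower <= 0 or self.upper <= self.lower:
                raise ValidationError("truncation bounds must be positive and ordered")

    def _dist(self):
        return stats.lognorm(s=self.log_sd, scale=math.exp(self.log_mean))

    def quantile(self, p) -> float:
        return self._dist().ppf(p)

    def truncation_mass(self) -> float:
        if self.lower is None:
            return 1.0
        d = self._dist()
        return float(d.cdf(self.upper) - d.cdf(self.lower))

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        """Lognormal draws; out-of-bound draws are rejected and redrawn."""
        if n < 1:
            raise ValidationError("n must be >= 1")
        rng = as_rng(seed)
        d = self._dist()
        if self.lower is None:
            return np.asarray(d.rvs(size=n, random_state=rng), dtype=float)
        if self.truncation_mass() < 1e-4:
            raise ValidationError("truncation interval has negligible probability mass")
        out = np.empty(n, dtype=float)
        filled = 0
        while filled < n:
            draw = np.asarray(d.rvs(size=max(n - filled, 16), random_state=rng))
            keep = draw[(draw >= self.lower) & (draw <= self.upper)][: n - filled]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out

    def as_dict(self) -> dict:
        return {
            "log_mean": self.log_mean,
            "log_sd": self.log_sd,
            "lower": self.lower,
            "upper": self.upper,
        }


def consumption_from_percentiles(targets) -> ConsumptionModel:
    """Calibrate (log_mean, log_sd) to percentile targets by least squares.

    ``targets`` is an iterable of (probability, g/day) pairs; with exactly two
    pairs the solution is exact.  Values must be positive and increasing in p.
    """
    pairs = sorted((float(p), float(v)) for p, v in targets)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 percentile targets")
    ps = np.array([p for p, _ in pairs])
    vs = np.array([v for _, v in pairs])
    if np.any((ps <= 0) | (ps >= 1)):
        raise ValidationError("target probabilities must lie in (0, 1)")
    if np.any(vs <= 0) or np.any(np.diff(vs) <= 0):
        raise ValidationError("target values must be positive and increasing in p")
    z = stats.norm.ppf(ps)
    A = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(A, np.log(vs), rcond=None)
    mu, sd = float(coef[0]), float(coef[1])
    if sd <= 0:
        raise ValidationError("targets imply non-positive log-sd")
    return ConsumptionModel(log_mean=mu, log_sd=sd)


@dataclass(frozen=True)
class DemographicGroup:
    label: str
    age_band: str
    sex: str
    weight_kg: float
    consumption: ConsumptionModel

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValidationError("body weight must be > 0")

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "age_band": self.age_band,
            "sex": self.sex,
            "weight_kg": self.weight_kg,
            "consumption": self.consumption.as_dict(),
        }


def read_demographics(path) -> list[DemographicGroup]:
    """Read groups from CSV or JSON.

    CSV columns: label, age_band, sex, weight_kg plus either
    (log_mean, log_sd) or percentile columns named like p50, p75, p95.
    JSON: a list of group objects in the same shape as ``as_dict()``, with an
    optional "percentiles" mapping instead of explicit log-params.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        groups = []
        for g in raw:
            if "consumption" in g:
                cons = ConsumptionModel(**g["consumption"])
            elif "percentiles" in g:
                cons = consumption_from_percentiles(
                    (float(k) / 100.0, v) for k, v in g["percentiles"].items()
                )
            else:
                raise ValidationError(f"group {g.get('label')} lacks consumption info")
            groups.append(
                DemographicGroup(
                    g["label"], g["age_band"], g["sex"], float(g["weight_kg"]), cons
                )
            )
        return groups
    df = pd.read_csv(path, comment="#")
    required = {"label", "age_band", "sex", "weight_kg"}
    if required - set(df.columns):
        raise ValidationError(f"demographics table missing {sorted(required - set(df.columns))}")
    pct_cols = [c for c in df.columns if c.lower().startswith("p") and c[1:].replace("_", ".").replace(".", "", 1).isdigit()]
    groups = []
    for _, row in df.iterrows():
        if "log_mean" in df.columns and not pd.isna(row.get("log_mean")):
            cons = ConsumptionModel(float(row["log_mean"]), float(row["log_sd"]))
        elif pct_cols:
            cons = consumption_from_percentiles(
                (float(c[1:].replace("_", ".")) / 100.0, float(row[c])) for c in pct_cols
            )
        else:
            raise ValidationError("demographics rows need log-params or percentile columns")
        groups.append(
            DemographicGroup(
                str(row["label"]), str(row["age_band"]), str(row["sex"]),
                float(row["weight_kg"]), cons,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_concentration(
    model,
    detection_rate: float,
    lod: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-inflated concentration draws.

    Each draw is the positive model's value with probability
    ``detection_rate`` and Uniform(0, LOD) otherwise.
    """
    if not 0.0 <= detection_rate <= 1.0:
        raise ValidationError("detection_rate must lie in [0, 1]")
    if lod <= 0:
        raise ValidationError("LOD must be > 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = as_rng(seed)
    detected = rng.uniform(size=n) < detection_rate
    out = rng.uniform(0.0, lod, size=n)
    n_pos = int(detected.sum())
    if n_pos:
        out[detected] = model.sample(n_pos, rng)
    return out


def compute_edi(cons, conc, weight: float) -> np.ndarray:
    """Paired per-iteration EDI in ug/(kg bw)/day."""
    cons = np.asarray(cons, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if cons.shape != conc.shape:
        raise ValidationError("consumption and concentration vectors must align")
    if weight <= 0:
        raise ValidationError("body weight must be > 0")
    if np.any(cons < 0) or np.any(conc < 0):
        raise ValidationError("inputs must be nonnegative")
    return cons * conc / weight


@dataclass(frozen=True)
class ExposureDistribution:
    """Simulated EDI draws for one analyte and demographic group."""

    analyte: str
    group: str
    draws: np.ndarray

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 1 or draws.size == 0:
            raise ValidationError("draws must be a non-empty vector")
        if np.any(draws < 0):
            raise ValidationError("EDI draws must be nonnegative")
        object.__setattr__(self, "draws", draws)

    @property
    def n_sim(self) -> int:
        return int(self.draws.size)

    def summary(self) -> dict[str, float]:
        return summarize(self.draws)

    def to_json(self, path=None, *, include_draws: bool = False, **extra) -> str:
        payload = {
            "analyte": self.analyte,
            "group": self.group,
            "n_sim": self.n_sim,
            "summary": self.summary(),
            **extra,
        }
        if include_draws:
            payload["draws"] = self.draws.tolist()
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def simulate_exposure(
    model,
    dataset_detection_rate: float,
    lod: float,
    group: DemographicGroup,
    analyte: str,
    n_sim: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> ExposureDistribution:
    """One Monte Carlo exposure run: concentration x consumption / weight.

    The concentration and consumption streams are drawn independently (no
    dependence is modelled) from a single generator.
    """
    rng = as_rng(seed)
    conc = simulate_concentration(model, dataset_detection_rate, lod, n_sim, rng)
    cons = group.consumption.sample(n_sim, rng)
    edi = compute_edi(cons, conc, group.weight_kg)
    return ExposureDistribution(analyte=analyte, group=group.label, draws=edi)
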