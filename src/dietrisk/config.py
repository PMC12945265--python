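"""Run configuration: YAML loading, validation, provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._utils import ValidationError
from .selection import CANDIDATE_LABELS

__all__ = ["AnalyteSettings", "RunConfig"]

_DEFAULT_CANDIDATES = (
    "lognormal", "weibull", "gamma", "exponential",
    "lognormal-gpd", "weibull-gpd", "gamma-gpd",
    "2-lognormal", "2-weibull", "2-gamma",
)

#: analytes with fewer positives than this are excluded from 2-component
#: mixture fitting (limited positives make EM unstable)
MIN_POSITIVES_FOR_MIXTURE = 30


@dataclass(frozen=True)
class AnalyteSettings:
    lod: float
    tdi: float | None = None
    rpf: float = 1.0
    group_tdi: float = 50.0

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValidationError("lod must be > 0")
        if self.tdi is not None and self.tdi <= 0:
            raise ValidationError("tdi must be > 0")


@dataclass(frozen=True)
class RunConfig:
    concentration: str
    demographics: str
    seed: int = 0
    n_sim: int = 10_000
    alpha: float = 0.05
    gof_B: int = 1000
    bootstrap_B: int = 100
    candidates: tuple[str, ...] = _DEFAULT_CANDIDATES
    shortlist_k: int = 3
    ic: str = "bic"
    aggregation: str = "lexicographic"
    min_positives_for_mixture: int = MIN_POSITIVES_FOR_MIXTURE
    analytes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sim < 1 or self.gof_B < 1 or self.bootstrap_B < 2:
            raise ValidationError("n_sim, gof_B and bootstrap_B must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.ic not in ("bic", "aic"):
            raise ValidationError("ic must be 'bic' or 'aic'")
        bad = set(self.candidates) - set(CANDIDATE_LABELS)
        if bad:
            raise ValidationError(f"unknown candidate labels: {sorted(bad)}")
        object.__setattr__(self, "candidates", tuple(self.candidates))
        analytes = {
            name: a if isinstance(a, AnalyteSettings) else AnalyteSettings(
                lod=float(a["lod"]),
                tdi=a.get("tdi"),
                rpf=float(a.get("rpf", 1.0)),
                group_tdi=float(a.get("group_tdi", 50.0)),
            )
            for name, a in self.analytes.items()
        }
        object.__setattr__(self, "analytes", analytes)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "candidates" in kwargs:
            kwargs["candidates"] = tuple(kwargs["candidates"])
        if "analytes" in kwargs:
            kwargs["analytes"] = {
                name: {k: v for k, v in a.items() if k in ("lod", "tdi", "rpf", "group_tdi")}
                for name, a in kwargs["analytes"].items()
            }
        missing = {"concentration", "demographics"} - set(kwargs)
        if missing:
            raise ValidationError(f"config {path} missing keys: {sorted(missing)}")
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["analytes"] = {k: asdict(v) for k, v in self.analytes.items()}
        return d

    def hash(self) -> str:
        """Short provenance hash embedded in every output."""
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}
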