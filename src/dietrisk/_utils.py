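"""Shared helpers: validation, RNG plumbing, decimal rounding."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["ValidationError", "FitError", "as_rng", "spawn_seed", "round_half_up"]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class FitError(RuntimeError):
    """Raised when an estimation routine cannot produce a usable fit."""


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed (or None, or an existing Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(master: int, name: str) -> np.random.SeedSequence:
    """Derive a named, replayable sub-stream from one master seed.

    The child stream depends only on (master, name), so individual pipeline
    stages can be replayed without re-running everything upstream.
    """
    return np.random.SeedSequence([int(master), zlib.crc32(name.encode("utf-8"))])


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties going away from zero, as report tables do.

    Python's builtin ``round`` is banker's rounding on binary floats
    (``round(0.0195, 3) == 0.019``), which disagrees with how published
    summary tables are rounded.
    """
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
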