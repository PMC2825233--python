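"""Small shared helpers: rounding and deterministic RNG derivation."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (printed-table convention).

    Python's built-in ``round`` is banker's rounding; every percentage and
    average printed by this package uses half-away-from-zero instead, so that
    e.g. 78.5 -> 79 and 4.025 -> 4.0 at their printed precisions.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    # nudge by an epsilon proportional to the magnitude to absorb float
    # representation error in values like 2.675 that decimal-print as halves
    eps = math.ulp(scaled) * 4
    return math.floor(abs(scaled) + 0.5 + eps) / factor * (1 if x >= 0 else -1)


def child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent generator for a named substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(stream)))
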