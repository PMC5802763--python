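"""Small shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of the source tables).

    Python's built-in ``round`` uses banker's rounding, which breaks the
    printed-percentage reproduction (e.g. 33.65 -> 33.6 instead of 33.7).
    """
    if not math.isfinite(x):
        return x
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-away-from-zero; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_away(100.0 * numerator / denominator, ndigits)


def as_binary_array(values, name: str) -> np.ndarray:
    """Coerce to a 0/1 integer array, rejecting anything else."""
    arr = np.asarray(values)
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        from .errors import ValidationError

        raise ValidationError(
            f"{name}: non-binary value {arr.ravel()[idx]!r} at position {idx}"
        )
    return arr.astype(np.int8)
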