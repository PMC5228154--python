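"""Kosambi mapping function.

The Kosambi function converts a recombination fraction r into an additive
genetic distance (centimorgans) while allowing a moderate level of crossover
interference:

    d(r) = 25 * ln((1 + 2r) / (1 - 2r))   [cM]

Its inverse is r(d) = tanh(d / 50) / 2.  Both are exposed in array form; the
forward function diverges as r -> 0.5, so r >= 0.5 is rejected.
"""
from __future__ import annotations

import numpy as np

from ..errors import InvalidConfigError

__all__ = ["kosambi", "kosambi_inverse"]


def kosambi(r):
    """Genetic distance in cM for recombination fraction ``r`` in [0, 0.5).

    Accepts scalars or arrays; raises :class:`InvalidConfigError` for any
    r outside [0, 0.5) (the distance is infinite at r = 0.5).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 0.5):
        raise InvalidConfigError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * arr) / (1.0 - 2.0 * arr))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def kosambi_inverse(d_cm):
    """Recombination fraction for a Kosambi distance ``d_cm`` >= 0 (cM)."""
    arr = np.asarray(d_cm, dtype=float)
    if np.any(arr < 0):
        raise InvalidConfigError("genetic distance must be non-negative")
    out = 0.5 * np.tanh(arr / 50.0)
    return float(out) if np.isscalar(d_cm) or arr.ndim == 0 else out
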