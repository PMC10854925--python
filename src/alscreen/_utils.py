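"""Small shared helpers: rounding and reproducible seed derivation."""

from __future__ import annotations

import math

import numpy as np

#: all derived seeds stay below 2**31 so they fit any RNG API we hand them to
_SEED_MOD = 2**31


def round_half_away(x: float) -> int:
    """Round with halves going away from zero (0.5 -> 1, -0.5 -> -1).

    Python's built-in ``round`` is banker's rounding; split sizes use this
    variant instead so that fractional set sizes are never biased downward.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def derive_seed(*parts: int) -> int:
    """Derive a child seed from an ordered tuple of integer parts.

    Uses :class:`numpy.random.SeedSequence`, which is stable across platforms
    and numpy versions, so a single master seed fans out to every stochastic
    component reproducibly.
    """
    entropy = [int(p) & 0xFFFFFFFF for p in parts]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0]) % _SEED_MOD
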