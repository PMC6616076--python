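"""Seed-derivation helpers.

Every stochastic component derives its generator from a master seed plus a
structured key (condition index, trial index, unit index) through
:class:`numpy.random.SeedSequence`, so that any artifact can be regenerated
from its manifest and so that paired comparisons (e.g. across candidate
parameter vectors during fitting) can reuse common random numbers.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

__all__ = ["seed_sequence", "generator"]


def seed_sequence(*key: int) -> np.random.SeedSequence:
    """Build a SeedSequence from a structured integer key.

    The key is typically ``(master_seed, condition_index, trial_index,
    unit_index)`` with trailing components omitted where not applicable.
    All components must be non-negative integers.
    """
    if not key:
        raise ValueError("seed key must have at least one component")
    for k in key:
        if int(k) != k or k < 0:
            raise ValueError(f"seed key components must be non-negative integers, got {key!r}")
    return np.random.SeedSequence([int(k) for k in key])


def generator(*key: int) -> np.random.Generator:
    """A PCG64 generator keyed by a structured integer tuple."""
    return np.random.Generator(np.random.PCG64(seed_sequence(*key)))


def spawn_generators(key: Sequence[int], n: int) -> list[np.random.Generator]:
    """``n`` independent generators derived from one structured key."""
    return [generator(*key, i) for i in range(n)]
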