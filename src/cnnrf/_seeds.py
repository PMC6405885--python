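"""Seed-derivation helpers.

Every stochastic operation in the package takes an explicit integer seed.
Derived seeds are produced from a master seed plus a tuple of integer keys via
``numpy.random.SeedSequence`` so that sub-computations (cells, folds, RF
repeats) are independently reproducible and independent of execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "rng_from"]

_MOD = 2**31 - 1


def derive_seed(master: int, *keys: int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and keys."""
    ss = np.random.SeedSequence([int(master) & 0xFFFFFFFF, *[int(k) & 0xFFFFFFFF for k in keys]])
    return int(ss.generate_state(1)[0] % _MOD)


def rng_from(seed: int, *keys: int) -> np.random.Generator:
    """A ``numpy`` Generator seeded from ``derive_seed(seed, *keys)``."""
    return np.random.default_rng(derive_seed(seed, *keys))
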