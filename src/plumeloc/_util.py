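"""Small shared helpers (RNG coercion, seed derivation)."""
from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_rngs(master_seed, *keys, n=1):
    """Derive independent, reproducible child generators from a master seed.

    The key tuple (location index, realization index, condition index, ...)
    makes every stream addressable, so conditions that share a prefix of the
    key can share random draws (common random numbers).
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in keys]])
    return [np.random.default_rng(c) for c in ss.spawn(n)]
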