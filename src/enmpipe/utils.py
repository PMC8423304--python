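"""Small shared helpers: reproducible seed derivation and logging."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("enmpipe")


def derive_seed(base_seed: int, *key: int) -> int:
    """Derive a stage seed from a global seed and an integer key path.

    Uses :class:`numpy.random.SeedSequence` so that distinct key paths give
    statistically independent streams while the whole run stays a pure
    function of the single global seed.  The result fits in a signed 32-bit
    int so it can seed scikit-learn estimators directly.
    """
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_from(base_seed: int, *key: int) -> np.random.Generator:
    """A Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(base_seed, *key))
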