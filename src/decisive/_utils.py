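"""Shared helpers: guard errors and RNG normalization."""
from __future__ import annotations

import numpy as np


class GuardError(RuntimeError):
    """Raised when an exact computation would exceed its configured size guard.

    The message names the guard so callers can raise it deliberately.
    """


def as_rng(seed_or_rng) -> np.random.Generator:
    """Return a numpy Generator from a seed, Generator, or SeedSequence."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
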