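"""Deterministic random-stream derivation.

One master seed per run; each component draws from its own substream keyed by
fixed integer tags, so adding a field to one component never perturbs the
draws of another.
"""

from __future__ import annotations

import numpy as np


def substream(seed: int, *key: int) -> np.random.Generator:
    """A generator seeded by (seed, *key) via SeedSequence — stable across runs."""
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), *[int(k) for k in key]]))
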