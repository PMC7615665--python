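"""Seed fan-out: one global integer seed yields independent per-stage streams."""

from __future__ import annotations

import numpy as np


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from one root seed."""
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def substream_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (for libraries wanting ints)."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1, np.uint64)[0] % (2**31 - 1)) for c in ss.spawn(n)]
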