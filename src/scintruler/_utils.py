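"""Internal helpers: seeding and RNG management."""

from __future__ import annotations

import contextlib
import random

import numpy as np

# SeedSequence-spawned children can exceed 2**31; keep user-visible seeds small.
_SEED_MOD = 2**31 - 1


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % _SEED_MOD for s in ss.generate_state(n, dtype=np.uint64)]


@contextlib.contextmanager
def seeded_stdlib_random(seed: int):
    """Temporarily seed Python's stdlib RNG, restoring prior state on exit.

    igraph's community detection draws from ``random``; this makes it
    reproducible without clobbering global state.
    """
    state = random.getstate()
    random.seed(int(seed))
    try:
        yield
    finally:
        random.setstate(state)
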