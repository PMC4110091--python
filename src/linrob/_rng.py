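"""Seed handling shared by every stochastic routine.

A single integer seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so pipeline stages can be re-run independently
yet reproducibly.
"""

from __future__ import annotations

import numpy as np

Seedlike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed=None) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible 31-bit child seed for a named pipeline stage."""
    entropy = np.random.SeedSequence(
        [int(global_seed) & 0x7FFFFFFF, _stage_key(stage)]
    )
    return int(entropy.generate_state(1)[0] % (2**31))


def _stage_key(stage: str) -> int:
    return int.from_bytes(stage.encode("utf8")[:8].ljust(8, b"\0"), "little") % (2**31)
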