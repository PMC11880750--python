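"""Deterministic seed splitting.

All randomness in a run flows from a single integer seed.  Each stage (or
simulator) derives its own independent stream by combining the run seed with
a stable label, so re-running one stage in isolation reproduces exactly the
stream it saw inside the full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "stage_rng"]


def derive_seed(seed: int, label: str) -> int:
    """Derive a child seed (< 2**31) from a run seed and a stage label."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """A Generator whose stream depends only on (seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )
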