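"""Named-stream seeding.

All randomness in the package flows from a single root seed.  Independent
sub-experiments (feature draws, noise, neighbors, ...) get their own stream
derived from the root seed plus a stable string key, so adding a stream never
perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, *path: object) -> np.random.Generator:
    """Return a Generator for the stream named by ``path`` under ``seed``."""
    keys = [zlib.crc32(str(p).encode("utf-8")) for p in path]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))
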