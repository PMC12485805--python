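"""Named, reproducible RNG substreams.

Every stochastic step of the simulator draws from its own substream derived
from (seed, step-name). This makes runs reproducible and keeps steps
independent: e.g. changing the number of cells does not perturb the peak-mean
draw, and a multi-group run with all factors set to 1 consumes the same
library-size / peak-mean / count streams as a single-type run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _key(name: str) -> int:
    # crc32 is stable across processes (unlike hash() on str)
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name),))
    return np.random.default_rng(ss)


def spawn_seed(seed: int, name: str) -> int:
    """Derive a child integer seed (< 2**31) for the named substream."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
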