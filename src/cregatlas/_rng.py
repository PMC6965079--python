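"""Named random streams.

One integer seed drives the whole synthetic bundle.  Each generator asks
for a child stream by *name*; the child is derived from the root seed and
a stable hash of the name, so adding a new generator never perturbs the
streams of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng"]


def _name_key(name: str) -> int:
    # stable across processes and Python versions (hash() is salted)
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of the root stream ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_name_key(name),))
    return np.random.Generator(np.random.PCG64(ss))
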