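"""Deterministic substream derivation from a single master seed.

Substreams are keyed by hashing human-readable labels (district, source,
parameter, stage ...) into the numpy SeedSequence entropy pool, so every
stratum gets an independent, platform-stable stream and adding one stratum
never perturbs another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _label_hash(label: str) -> int:
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")


def substream(seed: int, *labels: str) -> np.random.Generator:
    """An independent Generator for (seed, labels)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), *(_label_hash(l) for l in labels)])
    )


def subseed(seed: int, *labels: str) -> int:
    """A derived integer seed below 2**31 for APIs that take a plain seed."""
    ss = np.random.SeedSequence([int(seed), *(_label_hash(l) for l in labels)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
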