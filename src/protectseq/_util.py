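"""Small shared helpers: sequence ops, seeded RNG derivation, hashing."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= ALPHABET


def child_rng(seed: int, *offsets) -> np.random.Generator:
    """Derive an independent generator from a master seed and stable stage keys.

    Stage keys may be ints or short strings; strings are hashed stably so that
    reruns of a single stage reuse exactly the randomness of the full run.
    """
    ints = []
    for off in offsets:
        if isinstance(off, str):
            h = hashlib.sha256(off.encode()).digest()
            ints.append(int.from_bytes(h[:4], "big"))
        else:
            ints.append(int(off) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *ints]))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
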