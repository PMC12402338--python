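"""Small shared helpers: sequence codecs, Hamming distance, seeded RNG streams."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings.

    ``N`` (or any non-ACGT symbol) never matches anything, so it counts as a
    mismatch against every base.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x not in BASES)


def mismatches_capped(a: str, b: str, cap: int) -> int:
    """Number of mismatching positions, stopping early once ``cap`` is exceeded."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                return n
    return n


def random_dna_array(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """``n`` random DNA strings of ``length`` bases as a numpy unicode array."""
    if n == 0:
        return np.empty(0, dtype=f"U{max(length, 1)}")
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    raw = _BASE_BYTES[codes].tobytes()
    return np.frombuffer(raw, dtype=f"S{length}").astype(f"U{length}")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def stream(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from a base seed and a key.

    Every source of randomness in the package funnels through these streams so
    that a single integer seed fixes every draw.
    """
    return np.random.default_rng([int(seed)] + [int(k) for k in key])
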