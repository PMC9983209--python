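"""Canonical k-mer encoding shared by sketching, clustering and pseudomapping.

k-mers are packed 2 bits/base into uint64 (k <= 31), windows containing N
are dropped, and the canonical form is min(forward, reverse-complement)
of the packed integers. Hashing uses the splitmix64 finalizer, seeded by
xor so sketches are deterministic for a fixed hash seed.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Per-base 2-bit codes; -1 for N/invalid."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_codes(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Packed codes of every valid (N-free) k-mer of ``seq``, in order.

    With ``canonical`` each k-mer is replaced by min(kmer, revcomp(kmer)).
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    codes = encode_bases(seq)
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    win = win[valid].astype(np.uint64)
    if win.shape[0] == 0:
        return np.empty(0, dtype=np.uint64)
    pow_fwd = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = win @ pow_fwd
    if not canonical:
        return fwd
    pow_rev = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    rev = (np.uint64(3) - win) @ pow_rev
    return np.minimum(fwd, rev)


def kmer_set(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Sorted unique canonical k-mer codes of ``seq``."""
    return np.unique(kmer_codes(seq, k, canonical=canonical))


def splitmix64(x: np.ndarray, seed: int = 42) -> np.ndarray:
    """Vectorized splitmix64 finalizer; maps uint64 -> uint64 uniformly."""
    with np.errstate(over="ignore"):
        z = x.astype(np.uint64) ^ np.uint64(seed * 0x9E3779B97F4A7C15 % 2**64)
        z = (z + np.uint64(0x9E3779B97F4A7C15))
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z
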