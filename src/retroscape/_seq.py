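"""Low-level sequence helpers: 2-bit encoding, complement, mutation.

Sequences are held internally as numpy uint8 arrays with A,C,G,T -> 0,1,2,3.
Only unambiguous ACGT is supported; the simulator never emits anything else
and the readers reject other letters at the boundary.
"""
from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
# complement: A<->T (0<->3), C<->G (1<->2)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGT string."""
    return _DEC[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply point substitutions at per-site probability ``p``.

    Every substitution changes the base (shift by 1..3 mod 4, uniform).
    Returns (mutated copy, sorted array of mutated positions).
    """
    out = codes.copy()
    n = rng.binomial(codes.size, p)
    if n == 0:
        return out, np.empty(0, dtype=np.int64)
    pos = rng.choice(codes.size, size=n, replace=False)
    pos.sort()
    shift = rng.integers(1, 4, size=n, dtype=np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out, pos


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every overlapping k-mer into an int64 (first base = high bits)."""
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win @ powers
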