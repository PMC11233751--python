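"""Byte-level DNA helpers used by the vectorised code paths.

Sequences move through the pipeline either as Python strings (API surface)
or as uint8 arrays of ASCII codes (hot loops). The alphabet after input
normalisation is {A, C, G, T, N, -}.
"""
from __future__ import annotations

import numpy as np

from .errors import FormatError

A, C, G, T, N, GAP = (ord(b) for b in "ACGTN-")
DETERMINATE = np.array([A, C, G, T], dtype=np.uint8)

# IUPAC ambiguity codes (and U) collapse to N; case folds to upper.
_NORMALIZE = np.full(256, 0, dtype=np.uint8)
for _b in range(ord("A"), ord("Z") + 1):
    _NORMALIZE[_b] = N
    _NORMALIZE[_b + 32] = N
for _b in (A, C, G, T, N):
    _NORMALIZE[_b] = _b
    _NORMALIZE[_b + 32] = _b
_NORMALIZE[GAP] = GAP
_NORMALIZE[ord(".")] = GAP

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in ((A, T), (C, G), (G, C), (T, A)):
    _COMPLEMENT[_x] = _y
# N and '-' are self-complementary.

# ACGT -> 0..3 for error injection; 255 marks non-base codes.
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate((A, C, G, T)):
    _BASE_INDEX[_b] = _i
_INDEX_BASE = np.array([A, C, G, T], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """ASCII codes of *seq* as a uint8 array (no copy of semantics, just bytes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def normalize(seq: str, *, allow_gap: bool = True) -> str:
    """Upper-case *seq* and collapse ambiguity codes to N.

    Raises FormatError on characters that are not letters, '-' or '.'.
    """
    arr = _NORMALIZE[encode(seq)]
    if (arr == 0).any():
        bad = seq[int(np.argmax(arr == 0))]
        raise FormatError(f"invalid residue {bad!r} in sequence")
    if not allow_gap and (arr == GAP).any():
        raise FormatError("gap character not allowed here")
    return decode(arr)


def revcomp(seq: str) -> str:
    return decode(_COMPLEMENT[encode(seq)][::-1])


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis."""
    return _COMPLEMENT[arr][..., ::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int((encode(a) != encode(b)).sum())


def random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _INDEX_BASE[rng.integers(0, 4, n)]


def apply_substitution_errors(
    seqs: np.ndarray, rate: float, rng: np.random.Generator
) -> None:
    """In-place per-base substitution errors at *rate* on an (n, L) uint8 array.

    Each erroneous base is replaced by one of the three other bases uniformly.
    Non-ACGT codes are left untouched.
    """
    if rate <= 0:
        return
    mask = rng.random(seqs.shape, dtype=np.float32) < rate
    idx = _BASE_INDEX[seqs[mask]]
    mask[mask] = idx != 255  # never mutate N/gap
    idx = idx[idx != 255]
    shifted = (idx + rng.integers(1, 4, idx.size)) % 4
    seqs[mask] = _INDEX_BASE[shifted]


def substitute_sites(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Return a copy of 1-D *seq* with Bernoulli(rate) substitutions and the count."""
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    idx = _BASE_INDEX[out[mask]]
    keep = idx != 255
    pos = np.flatnonzero(mask)[keep]
    shifted = (idx[keep] + rng.integers(1, 4, keep.sum())) % 4
    out[pos] = _INDEX_BASE[shifted]
    return out, int(pos.size)
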