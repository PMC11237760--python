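"""Small shared sequence helpers (DNA strings, upper-case ACGTN)."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance; N counts as a mismatch against anything."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T; N excluded from numerator and denominator."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. bases with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return "".join(DNA[i] for i in idx)


def ungapped_identity(a: str, b: str) -> float:
    """Left-anchored ungapped identity: matches over length of the shorter."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


def encode(seq: str) -> np.ndarray:
    """Map ACGT→0..3, anything else→4, as uint8 (for vectorized scans)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out
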