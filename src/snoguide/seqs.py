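"""Small sequence utilities shared across the pipeline.

Genomic sequences are DNA over {A,C,G,T}; RNA (rRNA, snoRNA) is over
{A,C,G,U}. Base-pairing predicates treat T and U as equivalent.
"""
from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"

_DNA_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_RNA_COMP = str.maketrans("ACGUacgu", "UGCAugca")

# Watson-Crick pairs plus the G*U wobble, on the RNA alphabet.
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA (same strand)."""
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def is_wc(a: str, b: str) -> bool:
    return (a.upper().replace("T", "U"), b.upper().replace("T", "U")) in WC_PAIRS


def is_gu(a: str, b: str) -> bool:
    return (a.upper().replace("T", "U"), b.upper().replace("T", "U")) in GU_PAIRS


def pairs(a: str, b: str) -> bool:
    """True for any allowed pair (WC or wobble)."""
    key = (a.upper().replace("T", "U"), b.upper().replace("T", "U"))
    return key in WC_PAIRS or key in GU_PAIRS


def encode(seq: str, alphabet: str = DNA_ALPHABET) -> np.ndarray:
    """Sequence -> int array (index into alphabet). Raises on foreign symbols."""
    lut = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(arr < 0)[:5]})
        raise ValueError(f"sequence contains symbols outside {alphabet!r}: {bad}")
    return arr.astype(np.int64)


def random_sequence(rng: np.random.Generator, length: int, at_fraction: float,
                    alphabet: str = DNA_ALPHABET) -> str:
    """I.i.d. sequence with expected A+T(U) frequency ``at_fraction``."""
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    # alphabet order ACGT/ACGU -> probabilities (A, C, G, T/U)
    probs = np.array([p_at, p_gc, p_gc, p_at])
    idx = rng.choice(4, size=length, p=probs)
    return "".join(alphabet[i] for i in idx)


def base_frequencies(seq: str, alphabet: str = DNA_ALPHABET) -> np.ndarray:
    arr = encode(seq, alphabet)
    counts = np.bincount(arr, minlength=4).astype(float)
    return counts / counts.sum()
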