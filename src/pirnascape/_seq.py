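"""Low-level DNA sequence helpers shared across the pipeline.

Sequences are plain upper-case DNA strings (``A C G T N``); small RNAs are
stored T-not-U per FASTQ convention, so a "5′U" is a 5′T on the read.
Hot paths encode sequences as ``uint8`` numpy arrays of ASCII codes.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """ASCII byte encoding of a sequence, suitable for vectorized Hamming."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Hamming distance of equal-length strings; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
    return d


def phred_to_string(scores: np.ndarray) -> str:
    """Phred scores (integers) to a Phred+33 quality string."""
    return (np.asarray(scores, dtype=np.uint8) + 33).tobytes().decode("ascii")


def string_to_phred(qual: str) -> np.ndarray:
    return encode(qual).astype(np.int16) - 33


def mean_quality(qual: str) -> float:
    """Arithmetic mean Phred score of a quality string."""
    if not qual:
        return 0.0
    return float(string_to_phred(qual).mean())


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    return decode(encode(BASES)[rng.integers(0, 4, size=length)])
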