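"""Step 2: subtraction of known small-RNA classes.

A read is removed when it aligns end-to-end *within* some reference
sequence (either strand) with at most ``max_mismatch`` substitutions —
a defined, deterministic containment rule standing in for a database
screen. When a read matches references from several classes it is
attributed to the first class in the fixed order miRNA, rRNA, tRNA,
snRNA, snoRNA.

Matching is seed-and-verify on an exact k-mer index; reads too short for
the pigeonhole guarantee (length < 2k with one mismatch allowed) fall
back to an exhaustive scan over the (small) reference set.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

from ._seq import revcomp
from .types import SmallRNARead

CLASS_ORDER = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA")
DEFAULT_K = 7


class KnownRNAIndex:
    """Exact k-mer index over known-RNA references, both strands.

    ``sequences`` holds each deduplicated reference in both orientations;
    the index maps every k-mer to its (sequence, offset) postings.
    """

    def __init__(self, fasta_sets: dict[str, Sequence[tuple[str, str]]],
                 k: int = DEFAULT_K) -> None:
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.sequences: list[tuple[str, str, str]] = []  # (class, name, seq)
        self.index: dict[str, list[tuple[int, int]]] = {}
        seen: set[str] = set()
        n_refs = 0
        for cls in CLASS_ORDER:
            for name, seq in fasta_sets.get(cls, []):
                seq = seq.upper()
                n_refs += 1
                if seq in seen:
                    continue  # duplicate reference: postings deduplicated
                seen.add(seq)
                if len(seq) < k:
                    warnings.warn(f"reference {name} shorter than k={k}; skipped")
                    continue
                for oriented in (seq, revcomp(seq)):
                    sidx = len(self.sequences)
                    self.sequences.append((cls, name, oriented))
                    for off in range(len(oriented) - k + 1):
                        self.index.setdefault(oriented[off: off + k], []).append(
                            (sidx, off))
        if n_refs == 0:
            warnings.warn("building known-RNA index from an empty reference set")

    def n_kmers(self) -> int:
        return len(self.index)


def build_known_index(fasta_sets: dict[str, Sequence[tuple[str, str]]],
                      k: int = DEFAULT_K) -> KnownRNAIndex:
    """Build the known-RNA k-mer index from per-class reference sets."""
    return KnownRNAIndex(fasta_sets, k=k)


def _hamming_within(read: str, ref: str, offset: int, max_mm: int) -> bool:
    if offset < 0 or offset + len(read) > len(ref):
        return False
    mm = 0
    for a, b in zip(read, ref[offset: offset + len(read)]):
        if a != b or a == "N":
            mm += 1
            if mm > max_mm:
                return False
    return True


def classify_sequence(seq: str, index: KnownRNAIndex,
                      max_mismatch: int = 1) -> str | None:
    """Class label of the first-matching known-RNA class, or None."""
    k = index.k
    classes: set[str] = set()
    if len(seq) >= k * (max_mismatch + 1):
        # pigeonhole: one of max_mismatch+1 disjoint k-mer seeds is exact
        seeds = [(seq[i * k: (i + 1) * k], i * k) for i in range(max_mismatch + 1)]
        tried: set[tuple[int, int]] = set()
        for seed, soff in seeds:
            for sidx, off in index.index.get(seed, ()):
                key = (sidx, off - soff)
                if key in tried:
                    continue
                tried.add(key)
                cls, _, ref = index.sequences[sidx]
                if _hamming_within(seq, ref, off - soff, max_mismatch):
                    classes.add(cls)
    else:
        for cls, _, ref in index.sequences:
            if cls in classes:
                continue
            for off in range(len(ref) - len(seq) + 1):
                if _hamming_within(seq, ref, off, max_mismatch):
                    classes.add(cls)
                    break
    for cls in CLASS_ORDER:
        if cls in classes:
            return cls
    return None


def subtract_known(
    reads: Iterable[SmallRNARead],
    index: KnownRNAIndex,
    max_mismatch: int = 1,
) -> tuple[list[SmallRNARead], dict[str, int]]:
    """Remove known-RNA reads; returns (remaining, removed-per-class counts).

    ``remaining + removed == input`` exactly; identical sequences are
    classified once and the verdict cached.
    """
    remaining: list[SmallRNARead] = []
    removed = {cls: 0 for cls in CLASS_ORDER}
    cache: dict[str, str | None] = {}
    for r in reads:
        verdict = cache.get(r.sequence, "?")
        if verdict == "?":
            verdict = classify_sequence(r.sequence, index, max_mismatch)
            cache[r.sequence] = verdict
        if verdict is None:
            remaining.append(r)
        else:
            removed[verdict] += 1
    return remaining, removed
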