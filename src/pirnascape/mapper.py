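"""Step 3: all-hits genome mapping with at most one substitution.

The mapping contract is substitution-only (no indels), both strands,
reporting *every* placement with Hamming distance ≤ ``max_mismatch``
(default 1). Completeness comes from the pigeonhole principle: with one
mismatch allowed, one of two disjoint k-mer seeds must match exactly.
Two seed sizes are indexed so the guarantee holds for every read the
pipeline can see (k=12 for reads ≥ 24 nt, k=7 for 14–23 nt); shorter
reads fall back to seeding at every offset.

Scaffolds are concatenated into one byte array separated by pad bytes
that mismatch every base, so candidate verification is a single
vectorised window comparison; hits are then bounds-checked against the
owning scaffold.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .types import MappingRecord, SmallRNARead, StepCounts

DEFAULT_K = 12
DEFAULT_K_SHORT = 7
_PAD = 36  # longer than any read the pipeline accepts (35 nt)

_BASEVAL = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASEVAL[ord(_b)] = _i


class GenomeIndex:
    """Sorted k-mer code index over the concatenated genome."""

    def __init__(self, scaffolds: dict[str, str], k: int = DEFAULT_K,
                 k_short: int = DEFAULT_K_SHORT) -> None:
        if not 1 <= k_short <= k <= 13:
            raise ValueError("require 1 <= k_short <= k <= 13")
        self.k = k
        self.k_short = k_short
        self.names = list(scaffolds)
        self.lengths = np.array([len(scaffolds[n]) for n in self.names], dtype=np.int64)
        parts = []
        self.offsets = np.empty(len(self.names), dtype=np.int64)
        pos = 0
        pad = bytes([1]) * _PAD
        for i, name in enumerate(self.names):
            self.offsets[i] = pos
            parts.append(scaffolds[name].upper().encode("ascii"))
            parts.append(pad)
            pos += self.lengths[i] + _PAD
        self.arr = np.frombuffer(b"".join(parts), dtype=np.uint8).copy()
        # non-ACGT genome bytes (including pads) mismatch everything, reads' N included
        vals = _BASEVAL[self.arr]
        self.arr[vals < 0] = 1
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for kk in {k, k_short}:
            self._tables[kk] = self._build_table(vals, kk)

    def _build_table(self, vals: np.ndarray, k: int):
        n = len(vals) - k + 1
        if n <= 0:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        bad = (vals < 0).astype(np.int64)
        cbad = np.r_[0, np.cumsum(bad)]
        valid = (cbad[k:] - cbad[:-k]) == 0
        codes = np.zeros(n, dtype=np.int64)
        safe = np.where(vals < 0, 0, vals)
        for j in range(k):
            codes = codes * 4 + safe[j: j + n]
        pos = np.flatnonzero(valid)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        return (codes[order], pos[order])

    def lookup(self, code: int, k: int) -> np.ndarray:
        """Global start positions of an exact k-mer code."""
        sorted_codes, sorted_pos = self._tables[k]
        lo = np.searchsorted(sorted_codes, code, side="left")
        hi = np.searchsorted(sorted_codes, code, side="right")
        return sorted_pos[lo:hi]

    def scaffold_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    def n_indexed(self, k: int | None = None) -> int:
        return len(self._tables[k if k is not None else self.k][0])


def build_genome_index(scaffolds: dict[str, str], k: int = DEFAULT_K,
                       k_short: int = DEFAULT_K_SHORT) -> GenomeIndex:
    """Index a genome given as a name -> sequence dict."""
    return GenomeIndex(scaffolds, k=k, k_short=k_short)


def _seed_code(seq: str, start: int, k: int) -> int | None:
    code = 0
    for ch in seq[start: start + k]:
        v = _BASEVAL[ord(ch)]
        if v < 0:
            return None
        code = code * 4 + int(v)
    return code


def _candidate_starts(seq: str, index: GenomeIndex, max_mismatch: int) -> np.ndarray:
    m = len(seq)
    for k in (index.k, index.k_short):
        if m >= k * (max_mismatch + 1):
            seed_offsets = [i * k for i in range(max_mismatch + 1)]
            break
    else:
        k = index.k_short
        if m < k:
            return np.empty(0, dtype=np.int64)
        seed_offsets = list(range(0, m - k + 1))  # exhaustive seeding
    cands = []
    for off in seed_offsets:
        code = _seed_code(seq, off, k)
        if code is None:
            continue
        hits = index.lookup(code, k)
        if len(hits):
            cands.append(hits - off)
    if not cands:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(cands))


def _verify(seq_arr: np.ndarray, index: GenomeIndex, starts: np.ndarray,
            max_mismatch: int) -> tuple[np.ndarray, np.ndarray]:
    """Filter candidate global starts by Hamming distance and scaffold bounds."""
    m = len(seq_arr)
    total = len(index.arr)
    starts = starts[(starts >= 0) & (starts + m <= total)]
    if len(starts) == 0:
        return starts, np.empty(0, dtype=np.int64)
    windows = index.arr[starts[:, None] + np.arange(m)]
    mm = np.count_nonzero(windows != seq_arr, axis=1)
    ok = mm <= max_mismatch
    starts, mm = starts[ok], mm[ok]
    if len(starts) == 0:
        return starts, mm
    sidx = np.searchsorted(index.offsets, starts, side="right") - 1
    within = starts + m <= index.offsets[sidx] + index.lengths[sidx]
    return starts[within], mm[within]


def map_sequence(seq: str, index: GenomeIndex, max_mismatch: int = 1,
                 max_hits: int | None = None) -> list[tuple[int, int, str, int]]:
    """All placements of a sequence: (scaffold_idx, start, strand, mismatches),
    sorted by (scaffold, start, strand)."""
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        starts = _candidate_starts(s, index, max_mismatch)
        starts, mm = _verify(arr, index, starts, max_mismatch)
        for g, d in zip(starts, mm):
            sidx = int(np.searchsorted(index.offsets, g, side="right") - 1)
            out.append((sidx, int(g - index.offsets[sidx]), strand, int(d)))
    out.sort()
    if max_hits is not None:
        out = out[:max_hits]
    return out


def map_read(read: SmallRNARead | str, index: GenomeIndex,
             max_mismatch: int = 1,
             max_hits: int | None = None) -> list[MappingRecord]:
    """All-hits mapping of one read; empty list means unmapped."""
    if isinstance(read, SmallRNARead):
        seq, rid = read.sequence, read.id
    else:
        seq, rid = read, ""
    hits = map_sequence(seq, index, max_mismatch, max_hits)
    m = len(seq)
    return [
        MappingRecord(read_id=rid, scaffold=index.names[sidx], start=start,
                      end=start + m, strand=strand, mismatches=mm)
        for sidx, start, strand, mm in hits
    ]


_HIT_COLUMNS = ["read_id", "library", "scaffold", "start", "end", "strand", "mismatches"]


def map_library(
    reads: Sequence[SmallRNARead],
    index: GenomeIndex,
    max_mismatch: int = 1,
    max_hits: int | None = None,
    step_counts: StepCounts | None = None,
    library: str | None = None,
    hit_cache: dict[str, list[tuple[int, int, str, int]]] | None = None,
) -> tuple[pd.DataFrame, list[SmallRNARead]]:
    """Map a library; returns (hit table, mapped reads).

    A read survives Step 3 iff its hit list is non-empty. Identical
    sequences are mapped once and the hit list reused; pass ``hit_cache``
    (possibly shared across libraries) to retain sequence -> hits.
    """
    cache = hit_cache if hit_cache is not None else {}
    rows: dict[str, list] = {c: [] for c in _HIT_COLUMNS}
    mapped: list[SmallRNARead] = []
    n_unmapped = 0
    for r in reads:
        hits = cache.get(r.sequence)
        if hits is None:
            hits = map_sequence(r.sequence, index, max_mismatch, max_hits)
            cache[r.sequence] = hits
        if not hits:
            n_unmapped += 1
            continue
        mapped.append(r)
        m = len(r.sequence)
        for sidx, start, strand, mm in hits:
            rows["read_id"].append(r.id)
            rows["library"].append(r.library)
            rows["scaffold"].append(index.names[sidx])
            rows["start"].append(start)
            rows["end"].append(start + m)
            rows["strand"].append(strand)
            rows["mismatches"].append(mm)
    table = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    if len(table):
        table["start"] = table["start"].astype(np.int64)
        table["end"] = table["end"].astype(np.int64)
        table["mismatches"] = table["mismatches"].astype(np.int8)
    if step_counts is not None:
        lib = library if library is not None else (reads[0].library if len(reads) else "")
        step_counts.record(lib, "step3", len(mapped))
        step_counts.record_removed(lib, "step3_unmapped", n_unmapped)
    return table, mapped


def lite_hits_to_records(seq: str, hits: list[tuple[int, int, str, int]],
                         index: GenomeIndex) -> list[MappingRecord]:
    """Convert ``map_sequence`` tuples to :class:`MappingRecord` objects."""
    m = len(seq)
    return [MappingRecord(read_id="", scaffold=index.names[sidx], start=start,
                          end=start + m, strand=strand, mismatches=mm)
            for sidx, start, strand, mm in hits]


def hits_to_bed(table: pd.DataFrame) -> Iterable[tuple[str, int, int, str, int, str]]:
    """Hit table rows as BED6 tuples (score = mismatch count)."""
    for row in table.itertuples(index=False):
        yield (row.scaffold, int(row.start), int(row.end), row.read_id,
               int(row.mismatches), row.strand)
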