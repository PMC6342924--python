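"""Step 1 read processing: adapter trimming, quality/length filtering,
and length-distribution profiling.

The filtering contract follows standard small RNA-seq practice: the 3′
adapter is removed first, then reads with mean Phred ≤ 20 (computed on
the trimmed read), reads containing N, and reads outside 15–35 nt are
discarded. The bounds are inclusive; a mean of exactly 20.0 is removed.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import string_to_phred
from .types import SmallRNARead, StepCounts

DEFAULT_MIN_MEAN_QUALITY = 20.0
DEFAULT_LENGTH_RANGE = (15, 35)
DEFAULT_MIN_OVERLAP = 3


def trim_adapter(read: SmallRNARead, adapter: str,
                 min_overlap: int = DEFAULT_MIN_OVERLAP) -> SmallRNARead:
    """Remove the longest 3′ suffix of the read matching a prefix of the
    adapter, requiring at least ``min_overlap`` exactly matching bases.

    Reads with no qualifying suffix pass through unchanged. Qualities are
    trimmed in lockstep with the sequence.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    cut = _trim_point(read.sequence, adapter, min_overlap)
    if cut == len(read.sequence):
        return read
    return SmallRNARead(id=read.id, sequence=read.sequence[:cut],
                        qualities=read.qualities[:cut], library=read.library)


def _trim_point(seq: str, adapter: str, min_overlap: int) -> int:
    longest = min(len(seq), len(adapter))
    for n in range(longest, min_overlap - 1, -1):
        if seq.endswith(adapter[:n]):
            return len(seq) - n
    return len(seq)


def filter_step1(
    reads: Iterable[SmallRNARead],
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    step_counts: StepCounts | None = None,
    library: str | None = None,
) -> list[SmallRNARead]:
    """Apply the Step-1 filters; optionally record attrition in ``step_counts``.

    A read survives iff mean Phred > ``min_mean_quality`` (strict), it
    contains no N, and its length lies in ``length_range`` inclusive.
    """
    lo, hi = length_range
    kept: list[SmallRNARead] = []
    n_raw = n_quality = n_n = n_length = 0
    for r in reads:
        n_raw += 1
        if not (lo <= len(r.sequence) <= hi):
            n_length += 1
            continue
        if "N" in r.sequence:
            n_n += 1
            continue
        if _mean_q(r.qualities) <= min_mean_quality:
            n_quality += 1
            continue
        kept.append(r)
    if step_counts is not None:
        lib = library if library is not None else (kept[0].library if kept else "")
        step_counts.record(lib, "raw", n_raw)
        step_counts.record(lib, "step1", len(kept))
        step_counts.record_removed(lib, "step1_length", n_length)
        step_counts.record_removed(lib, "step1_N", n_n)
        step_counts.record_removed(lib, "step1_quality", n_quality)
    return kept


def _mean_q(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.mean(string_to_phred(qual)))


def length_histogram(reads: Iterable[SmallRNARead]) -> pd.DataFrame:
    """Per-library read-length fractions (columns: library, length, fraction).

    Fractions sum to 1 within each library; empty input gives an empty table.
    """
    counts: Counter[tuple[str, int]] = Counter()
    totals: Counter[str] = Counter()
    for r in reads:
        counts[(r.library, len(r.sequence))] += 1
        totals[r.library] += 1
    rows = [
        {"library": lib, "length": length, "count": n,
         "fraction": n / totals[lib]}
        for (lib, length), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["library", "length", "count", "fraction"])


def modal_lengths(hist: pd.DataFrame, library: str, n: int = 2) -> list[int]:
    """The ``n`` most frequent read lengths of a library, by fraction."""
    sub = hist[hist["library"] == library]
    return list(sub.nlargest(n, "fraction")["length"])


def process_library(
    reads: Sequence[SmallRNARead],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    step_counts: StepCounts | None = None,
    library: str | None = None,
) -> list[SmallRNARead]:
    """Trim + filter one library (the complete Step 1)."""
    trimmed = (trim_adapter(r, adapter, min_overlap) for r in reads)
    return filter_step1(trimmed, min_mean_quality, length_range,
                        step_counts=step_counts, library=library)
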