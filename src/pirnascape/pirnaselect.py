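"""Step 4: putative piRNA selection and characterisation.

Mapped reads in the 26–31 nt window are selected as putative piRNAs,
collapsed to unique sequences with per-library counts, and profiled:
reads-per-million (RPM), 5′-terminal base composition (the position-1 T
fraction is the "5′U" statistic), and the mapping-locus distribution
with its unique-locus / multi-locus / multi-tandem partition
("multi-tandem" = at least two placements on a single scaffold).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import MappingRecord, SmallRNARead, StepCounts, UniqueSequenceRecord

DEFAULT_SIZE_RANGE = (26, 31)

LOCUS_CLASSES = ("unique-locus", "multi-locus", "multi-tandem")


def select_pirnas(
    mapped_reads: Iterable[SmallRNARead],
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    step_counts: StepCounts | None = None,
    library: str | None = None,
) -> list[SmallRNARead]:
    """Keep mapped reads whose length lies in ``size_range`` inclusive."""
    lo, hi = size_range
    kept, dropped = [], 0
    for r in mapped_reads:
        if lo <= len(r.sequence) <= hi:
            kept.append(r)
        else:
            dropped += 1
    if step_counts is not None:
        lib = library if library is not None else (kept[0].library if kept else "")
        step_counts.record(lib, "step4", len(kept))
        step_counts.record_removed(lib, "step4_size", dropped)
    return kept


def collapse_unique(
    pirna_reads: Iterable[SmallRNARead],
    hit_lists: dict[str, list[MappingRecord]],
) -> list[UniqueSequenceRecord]:
    """Collapse piRNA reads to unique sequences with per-library counts.

    ``hit_lists`` maps sequence -> all-hits placement list (identical
    sequences necessarily share one hit list under the mapping contract);
    a sequence missing from ``hit_lists`` is a contract violation.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for r in pirna_reads:
        counts[r.sequence][r.library] += 1
    records = []
    for seq, per_lib in counts.items():
        if seq not in hit_lists:
            raise RuntimeError(f"no hit list for selected sequence {seq}: "
                               "mapper contract violated")
        records.append(UniqueSequenceRecord(sequence=seq, counts=dict(per_lib),
                                            loci=list(hit_lists[seq])))
    records.sort(key=lambda u: u.sequence)
    return records


def hit_lists_from_table(table: pd.DataFrame,
                         reads: Iterable[SmallRNARead]) -> dict[str, list[MappingRecord]]:
    """Sequence -> placement list, reconstructed from a mapping hit table."""
    by_read: dict[str, list[MappingRecord]] = defaultdict(list)
    for row in table.itertuples(index=False):
        by_read[row.read_id].append(MappingRecord(
            read_id=row.read_id, scaffold=row.scaffold, start=int(row.start),
            end=int(row.end), strand=row.strand, mismatches=int(row.mismatches)))
    out: dict[str, list[MappingRecord]] = {}
    for r in reads:
        if r.sequence not in out and r.id in by_read:
            out[r.sequence] = by_read[r.id]
    return out


def compute_rpm(count: int, library_total: int) -> float:
    """RPM = (read count / total piRNA reads of the library) × 10^6."""
    if library_total <= 0:
        raise ValueError("library_total must be positive for RPM")
    return count / library_total * 1e6


def add_rpm(records: Sequence[UniqueSequenceRecord],
            library_totals: dict[str, int] | None = None) -> None:
    """Fill per-library RPM on each record, in place.

    Totals default to the per-library sums over the records themselves
    (i.e. the library's Step-4 piRNA read count).
    """
    if library_totals is None:
        library_totals = Counter()
        for u in records:
            for lib, n in u.counts.items():
                library_totals[lib] += n
    for u in records:
        u.rpm = {lib: compute_rpm(n, library_totals[lib])
                 for lib, n in u.counts.items()}


def base_composition(
    records: Sequence[UniqueSequenceRecord],
    n_positions: int = 10,
    weighted: bool = False,
) -> pd.DataFrame:
    """Base-fraction matrix over the first ``n_positions`` 5′ positions.

    Rows are 1-based positions, columns A/C/G/T; each row sums to 1 over
    the sequences long enough to contribute. Unweighted (default) counts
    each unique sequence once; ``weighted=True`` weights by total read
    count. The position-1 T fraction is the 5′U statistic.
    """
    mat = np.zeros((n_positions, 4))
    cols = {b: i for i, b in enumerate("ACGT")}
    for u in records:
        w = u.total_count if weighted else 1
        for p in range(min(n_positions, len(u.sequence))):
            j = cols.get(u.sequence[p])
            if j is not None:
                mat[p, j] += w
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mat / totals, 0.0)
    return pd.DataFrame(frac, index=pd.RangeIndex(1, n_positions + 1, name="position"),
                        columns=list("ACGT"))


def five_prime_u_fraction(records: Sequence[UniqueSequenceRecord],
                          weighted: bool = False) -> float:
    """Fraction of (unique or read-weighted) piRNAs starting with T."""
    comp = base_composition(records, n_positions=1, weighted=weighted)
    return float(comp.loc[1, "T"])


def locus_distribution(
    records: Sequence[UniqueSequenceRecord],
    min_reads: int = 0,
) -> tuple[pd.Series, dict[str, float]]:
    """Histogram of per-sequence locus counts plus class fractions.

    ``min_reads`` restricts to sequences with total read count strictly
    greater than the threshold (the "reads > 1" display filter uses
    ``min_reads=1``). Class fractions are over unique sequences and
    partition to 1.
    """
    use = [u for u in records if u.total_count > min_reads]
    hist = Counter(u.n_loci for u in use)
    tallies = Counter(u.locus_class for u in use)
    n = len(use)
    fractions = {cls: (tallies.get(cls, 0) / n if n else 0.0)
                 for cls in LOCUS_CLASSES}
    series = pd.Series(dict(sorted(hist.items())), dtype=int, name="n_sequences")
    series.index.name = "n_loci"
    return series, fractions


def unique_table(records: Sequence[UniqueSequenceRecord],
                 libraries: Sequence[str]) -> pd.DataFrame:
    """Unique-sequence summary table (one row per sequence)."""
    rows = []
    for u in records:
        row = {"sequence": u.sequence, "n_loci": u.n_loci,
               "n_scaffolds": u.n_scaffolds, "class": u.locus_class}
        for lib in libraries:
            row[f"count_{lib}"] = u.counts.get(lib, 0)
            row[f"rpm_{lib}"] = u.rpm.get(lib, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
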