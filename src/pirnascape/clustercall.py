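"""piRNA cluster calling from the all-hits mapping table.

A cluster is a run of mapping loci on one scaffold in which consecutive
hits are separated by a gap of at most ``merge_distance`` (strand-
agnostic single-linkage; the transitive closure makes regions maximal
and disjoint), retained when at least ``min_coverage`` placements
overlap it, pooled over all libraries. Multi-mapped reads contribute at
every placement by default (a count-once-per-read mode is available).
Cluster expression is RPKM normalised by *genomic* cluster length:

    RPKM = (reads in cluster × 10^6) / (library piRNA total × length in kb)

Directionality labels a cluster unidirectional when at least
``threshold`` of its placements fall on one strand, else bidirectional.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import Cluster

DEFAULT_MERGE_DISTANCE = 1000
DEFAULT_MIN_COVERAGE = 6
DEFAULT_DIRECTION_THRESHOLD = 0.8

_REGION_COLUMNS = ["scaffold", "start", "end"]


def merge_loci(mappings: pd.DataFrame,
               merge_distance: int = DEFAULT_MERGE_DISTANCE) -> pd.DataFrame:
    """Merge mapping loci into maximal regions (gap ≤ ``merge_distance``).

    Two hits join when the gap between their intervals is at most the
    merge distance (touching or overlapping intervals always join); the
    result is the transitive closure, sorted by (scaffold, start).
    """
    if len(mappings) == 0:
        return pd.DataFrame(columns=_REGION_COLUMNS)
    df = mappings[["scaffold", "start", "end"]].sort_values(
        ["scaffold", "start", "end"], kind="stable")
    rows = []
    for scaffold, sub in df.groupby("scaffold", sort=True):
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        # a new region opens where the gap to everything before exceeds d
        breaks = np.flatnonzero(starts[1:] - ends[:-1] > merge_distance) + 1
        bounds = np.r_[0, breaks, len(starts)]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            rows.append((scaffold, int(starts[b0]), int(ends[b1 - 1])))
    return pd.DataFrame(rows, columns=_REGION_COLUMNS)


def assign_to_regions(mappings: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Region index (or -1) for each mapping row, by ≥1 bp overlap.

    Regions must be disjoint per scaffold; a placement overlapping a
    region by at least one base is assigned to it.
    """
    out = np.full(len(mappings), -1, dtype=np.int64)
    if len(mappings) == 0 or len(regions) == 0:
        return out
    region_pos = {}
    for scaffold, sub in regions.groupby("scaffold"):
        region_pos[scaffold] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                                sub.index.to_numpy())
    mpos = np.arange(len(mappings))
    for scaffold, sub in mappings.groupby("scaffold"):
        if scaffold not in region_pos:
            continue
        rs, re, ridx = region_pos[scaffold]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        j = np.searchsorted(rs, s, side="right") - 1
        ok = j >= 0
        ok &= np.where(ok, s < re[np.clip(j, 0, None)], False)
        # an interval starting before region j could still overlap region j+1
        j2 = np.clip(j + 1, None, len(rs) - 1)
        ok2 = (~ok) & (e > rs[j2]) & (s < re[j2])
        out[mpos[mappings["scaffold"] == scaffold][ok]] = ridx[j[ok]]
        out[mpos[mappings["scaffold"] == scaffold][ok2]] = ridx[j2[ok2]]
    return out


def coverage_filter(
    regions: pd.DataFrame,
    mappings: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    library_totals: dict[str, int] | None = None,
    direction_threshold: float = DEFAULT_DIRECTION_THRESHOLD,
    count_multimaps: bool = True,
) -> list[Cluster]:
    """Promote regions with pooled coverage ≥ ``min_coverage`` to clusters.

    Coverage counts mapping placements overlapping the region by ≥1 bp,
    summed over all libraries (every placement of a multi-mapped read by
    default; with ``count_multimaps=False`` each read counts once per
    region). Clusters are named ``<scaffold>.cl<n>`` in coordinate order
    within each scaffold. RPKM is filled when ``library_totals`` (total
    piRNA reads per library) is given.
    """
    if len(regions) == 0:
        return []
    assigned = assign_to_regions(mappings, regions)
    mask = assigned >= 0
    cols = ["library", "strand"] + (["read_id"] if not count_multimaps else [])
    work = mappings.loc[mask, cols].copy()
    work["_region"] = assigned[mask]
    if not count_multimaps:
        work = work.drop_duplicates(subset=["read_id", "library", "_region"])

    totals = work.groupby("_region").size()
    lib_counts = work.groupby(["_region", "library"]).size()
    plus_counts = work[work["strand"] == "+"].groupby("_region").size()

    clusters: list[Cluster] = []
    ordinal: dict[str, int] = {}
    for ridx, row in regions.sort_values(["scaffold", "start"]).iterrows():
        cov = int(totals.get(ridx, 0))
        if cov < min_coverage or cov == 0:
            continue
        scaffold = row["scaffold"]
        ordinal[scaffold] = ordinal.get(scaffold, 0) + 1
        plus = int(plus_counts.get(ridx, 0))
        label, pf = directionality(plus, cov - plus, direction_threshold)
        counts = {lib: int(n) for lib, n in lib_counts.loc[ridx].items()}
        cl = Cluster(name=f"{scaffold}.cl{ordinal[scaffold]}", scaffold=scaffold,
                     start=int(row["start"]), end=int(row["end"]),
                     counts=counts, plus_fraction=pf, directionality=label)
        if library_totals:
            cl.rpkm = {lib: cluster_rpkm(n, library_totals[lib], cl.length)
                       for lib, n in cl.counts.items() if library_totals.get(lib)}
        clusters.append(cl)
    return clusters


def cluster_rpkm(count: int, library_total: int, length_bp: int) -> float:
    """Genomic-length RPKM of a cluster for one library."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if length_bp <= 0:
        raise ValueError("cluster length must be positive")
    return count * 1e6 / (library_total * length_bp / 1000)


def directionality(plus_hits: int, minus_hits: int,
                   threshold: float = DEFAULT_DIRECTION_THRESHOLD) -> tuple[str, float]:
    """Strand label and plus-fraction from per-strand hit counts."""
    total = plus_hits + minus_hits
    if total == 0:
        raise ValueError("directionality needs at least one overlapping mapping")
    pf = plus_hits / total
    if pf >= threshold:
        return "unidirectional+", pf
    if pf <= 1 - threshold:
        return "unidirectional-", pf
    return "bidirectional", pf


def call_clusters(
    mappings: pd.DataFrame,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    library_totals: dict[str, int] | None = None,
    direction_threshold: float = DEFAULT_DIRECTION_THRESHOLD,
    count_multimaps: bool = True,
) -> list[Cluster]:
    """Merge + coverage-filter in one call."""
    regions = merge_loci(mappings, merge_distance)
    return coverage_filter(regions, mappings, min_coverage,
                           library_totals=library_totals,
                           direction_threshold=direction_threshold,
                           count_multimaps=count_multimaps)


def sensitivity_grid(mappings: pd.DataFrame, distances: Sequence[int],
                     coverages: Sequence[int]) -> pd.DataFrame:
    """Cluster counts for every (merge distance, min coverage) pair.

    Rows are distances, columns coverage floors; counts are non-
    increasing along each row (raising the floor can only drop clusters).
    """
    grid = np.zeros((len(distances), len(coverages)), dtype=int)
    for i, d in enumerate(distances):
        regions = merge_loci(mappings, d)
        assigned = assign_to_regions(mappings, regions)
        cov = pd.Series(assigned[assigned >= 0]).value_counts()
        for j, c in enumerate(coverages):
            grid[i, j] = int((cov >= c).sum())
    return pd.DataFrame(grid, index=pd.Index(distances, name="merge_distance"),
                        columns=pd.Index(coverages, name="min_coverage"))


def dot_matrix(sequence: str, word: int = 10) -> set[tuple[int, int]]:
    """Self-comparison dot matrix: all (i, j) with identical ``word``-mers.

    Symmetric and containing the main diagonal; off-diagonal runs mark
    repeats (for a tandem array of unit u, a run at offset u).
    """
    if word > len(sequence):
        raise ValueError("word size exceeds sequence length")
    positions: dict[str, list[int]] = {}
    for i in range(len(sequence) - word + 1):
        positions.setdefault(sequence[i: i + word], []).append(i)
    dots: set[tuple[int, int]] = set()
    for pos in positions.values():
        for i in pos:
            for j in pos:
                dots.add((i, j))
    return dots


def clusters_table(clusters: Sequence[Cluster], libraries: Sequence[str]) -> pd.DataFrame:
    """Cluster summary table (one row per cluster)."""
    rows = []
    for cl in clusters:
        row = {"name": cl.name, "scaffold": cl.scaffold, "start": cl.start,
               "end": cl.end, "length": cl.length,
               "plus_fraction": cl.plus_fraction,
               "directionality": cl.directionality}
        for lib in libraries:
            row[f"count_{lib}"] = cl.counts.get(lib, 0)
            row[f"rpkm_{lib}"] = cl.rpkm.get(lib, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def clusters_to_bed(clusters: Sequence[Cluster]):
    for cl in clusters:
        strand = {"unidirectional+": "+", "unidirectional-": "-"}.get(
            cl.directionality, ".")
        yield (cl.scaffold, cl.start, cl.end, cl.name,
               sum(cl.counts.values()), strand)


def coverage_bedgraph(mappings: pd.DataFrame):
    """Per-base pooled coverage as bedGraph rows (zero runs omitted)."""
    for scaffold, sub in mappings.groupby("scaffold"):
        edges = np.unique(np.r_[sub["start"].to_numpy(), sub["end"].to_numpy()])
        delta = np.zeros(len(edges), dtype=np.int64)
        delta += np.bincount(np.searchsorted(edges, sub["start"].to_numpy()),
                             minlength=len(edges))
        delta -= np.bincount(np.searchsorted(edges, sub["end"].to_numpy()),
                             minlength=len(edges))
        depth = np.cumsum(delta)
        for i in range(len(edges) - 1):
            if depth[i] > 0:
                yield (scaffold, int(edges[i]), int(edges[i + 1]), float(depth[i]))


def reciprocal_overlap_match(
    called: Sequence[Cluster],
    truth: pd.DataFrame,
    min_fraction: float = 0.5,
) -> dict[str, float]:
    """Score called clusters against planted truth intervals.

    A called/truth pair matches when their overlap covers at least
    ``min_fraction`` of *both* intervals (same scaffold); matching is
    greedy one-to-one by decreasing overlap. Returns recall, precision
    and F1 over the truth/called sets.
    """
    pairs = []
    truth_iv = list(truth[["scaffold", "start", "end"]].itertuples(index=True))
    for ci, cl in enumerate(called):
        for t in truth_iv:
            if t.scaffold != cl.scaffold:
                continue
            ov = min(cl.end, t.end) - max(cl.start, t.start)
            if ov <= 0:
                continue
            if ov >= min_fraction * (cl.end - cl.start) and \
               ov >= min_fraction * (t.end - t.start):
                pairs.append((ov, ci, t.Index))
    pairs.sort(reverse=True)
    used_c: set[int] = set()
    used_t: set = set()
    matched: list[tuple[int, object]] = []
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matched.append((ci, ti))
    recall = len(used_t) / len(truth_iv) if truth_iv else 1.0
    precision = len(used_c) / len(called) if called else 1.0
    f1 = (0.0 if recall + precision == 0
          else 2 * recall * precision / (recall + precision))
    return {"recall": recall, "precision": precision, "f1": f1,
            "n_called": len(called), "n_truth": len(truth_iv),
            "n_matched": len(used_t), "pairs": matched}
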