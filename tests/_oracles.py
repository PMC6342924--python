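"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (exhaustive scans, O(n^2)
closures, textbook definitions) and shares no code with the package's
algorithmic paths.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def exhaustive_hits(seq: str, scaffolds: dict[str, str], max_mm: int = 1):
    """Every placement of seq (both strands) with Hamming distance ≤ max_mm,
    by full sliding-window scan. Returns sorted (scaffold_idx, start,
    strand, mismatches) tuples; N never matches anything."""
    out = []
    for si, (_, g) in enumerate(scaffolds.items()):
        garr = np.frombuffer(g.encode(), dtype=np.uint8).copy()
        garr[garr == ord("N")] = 0  # genome N matches nothing, including read N
        for strand, s in (("+", seq), ("-", rc(seq))):
            sarr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
            sarr[sarr == ord("N")] = 1
            m = len(sarr)
            if m > len(garr):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(garr, m)
            mm = (windows != sarr).sum(axis=1)
            for pos in np.flatnonzero(mm <= max_mm):
                out.append((si, int(pos), strand, int(mm[pos])))
    return sorted(out)


def exhaustive_hits_batch(seqs: list[str], scaffolds: dict[str, str],
                          max_mm: int = 1, chunk: int = 64):
    """``exhaustive_hits`` for many sequences, vectorised by read length."""
    results: list[list] = [[] for _ in seqs]
    order = {}
    for i, s in enumerate(seqs):
        order.setdefault(len(s), []).append(i)
    for si, (_, g) in enumerate(scaffolds.items()):
        garr = np.frombuffer(g.encode(), dtype=np.uint8).copy()
        garr[garr == ord("N")] = 0
        for m, idxs in order.items():
            if m > len(garr):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(garr, m)
            for strand in "+-":
                for c0 in range(0, len(idxs), chunk):
                    block = idxs[c0: c0 + chunk]
                    mats = []
                    for i in block:
                        s = seqs[i] if strand == "+" else rc(seqs[i])
                        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
                        arr[arr == ord("N")] = 1
                        mats.append(arr)
                    reads = np.stack(mats)
                    mm = (windows[None, :, :] != reads[:, None, :]).sum(axis=2)
                    for row, i in enumerate(block):
                        for pos in np.flatnonzero(mm[row] <= max_mm):
                            results[i].append((si, int(pos), strand,
                                               int(mm[row, pos])))
    return [sorted(r) for r in results]


def closure_merge(intervals: list[tuple[int, int]], d: int) -> list[tuple[int, int]]:
    """O(n^2) transitive-closure interval merging: two intervals join when
    their gap is ≤ d; repeat until fixpoint."""
    regions = [list(iv) for iv in intervals]
    while True:
        out: list[list[int]] = []
        for s, e in regions:
            for r in out:
                gap = max(s - r[1], r[0] - e)
                if gap <= d:
                    r[0], r[1] = min(r[0], s), max(r[1], e)
                    break
            else:
                out.append([s, e])
        if len(out) == len(regions):  # fixpoint: no pair merged this pass
            return sorted((s, e) for s, e in out)
        regions = out


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def contained_with_mismatches(read: str, refs: list[str], max_mm: int) -> bool:
    """Is the read end-to-end within any reference (either strand) with
    ≤ max_mm substitutions? Plain nested-loop scan."""
    for ref in refs:
        for oriented in (ref, rc(ref)):
            for off in range(len(oriented) - len(read) + 1):
                window = oriented[off: off + len(read)]
                mm = sum(1 for a, b in zip(read, window) if a != b or a == "N")
                if mm <= max_mm:
                    return True
    return False


def fisher_two_sided_hypergeom(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by summing hypergeometric point masses no
    larger than the observed one."""
    from scipy.stats import hypergeom

    n = a + b + c + d
    K = a + b  # row 1 total
    N1 = a + c  # column 1 total
    lo = max(0, K + N1 - n)
    hi = min(K, N1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, K, N1)
    observed = hypergeom.pmf(a, n, K, N1)
    return float(pmf[pmf <= observed * (1 + 1e-9)].sum())
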