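"""Cluster calling: merging, coverage, RPKM, directionality, dot matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnascape.clustercall import (assign_to_regions, call_clusters,
                                    cluster_rpkm, coverage_filter,
                                    directionality, dot_matrix, merge_loci,
                                    reciprocal_overlap_match, sensitivity_grid)

from _oracles import closure_merge


def _mappings(intervals, scaffold="s1", strand="+", lib="L"):
    return pd.DataFrame({
        "read_id": [f"r{i}" for i in range(len(intervals))],
        "library": lib, "scaffold": scaffold,
        "start": [s for s, _ in intervals], "end": [e for _, e in intervals],
        "strand": strand, "mismatches": 0})


def test_merge_gap_boundary():
    # gap exactly 1000 merges; 1001 does not
    one = merge_loci(_mappings([(100, 130), (1130, 1160)]), 1000)
    assert one[["start", "end"]].values.tolist() == [[100, 1160]]
    two = merge_loci(_mappings([(100, 130), (1131, 1161)]), 1000)
    assert len(two) == 2
    single = merge_loci(_mappings([(5, 40)]), 1000)
    assert single[["start", "end"]].values.tolist() == [[5, 40]]


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 80)),
                min_size=1, max_size=60),
       st.integers(0, 500))
def test_merge_equals_transitive_closure_oracle(iv_spec, d):
    intervals = [(s, s + L) for s, L in iv_spec]
    got = merge_loci(_mappings(intervals), d)
    assert got[["start", "end"]].apply(tuple, axis=1).tolist() == \
        closure_merge(intervals, d)


def test_merged_regions_disjoint_with_gap(rng):
    intervals = [(int(s), int(s) + int(rng.integers(20, 50)))
                 for s in rng.integers(0, 20000, size=300)]
    d = 150
    regions = merge_loci(_mappings(intervals), d)
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    assert (starts[1:] - ends[:-1] > d).all()


def test_coverage_boundary_six_reads():
    five = _mappings([(100, 130)] * 5)
    six = _mappings([(100, 130)] * 6)
    regions = merge_loci(six, 1000)
    assert coverage_filter(regions, five, min_coverage=6) == []
    accepted = coverage_filter(regions, six, min_coverage=6)
    assert len(accepted) == 1 and accepted[0].start == 100


def test_coverage_equals_bruteforce_overlap_count(rng):
    intervals = [(int(s), int(s) + 30) for s in rng.integers(0, 15000, size=400)]
    m = _mappings(intervals)
    regions = merge_loci(m, 200)
    assigned = assign_to_regions(m, regions)
    for ridx, row in regions.iterrows():
        brute = sum(1 for s, e in intervals if s < row["end"] and e > row["start"])
        assert (assigned == ridx).sum() == brute


def test_cluster_naming_in_scaffold_order(rng):
    m = pd.concat([_mappings([(100, 130)] * 6, scaffold="s2"),
                   _mappings([(5000, 5030)] * 6, scaffold="s2"),
                   _mappings([(10, 40)] * 7, scaffold="s1")], ignore_index=True)
    clusters = call_clusters(m, 1000, 6)
    assert [c.name for c in clusters] == ["s1.cl1", "s2.cl1", "s2.cl2"]


def test_rpkm_algebra():
    assert cluster_rpkm(100, 10 ** 6, 1000) == 100.0
    base = cluster_rpkm(57, 3_000_000, 1700)
    # doubling counts and totals leaves RPKM unchanged
    assert np.isclose(cluster_rpkm(114, 6_000_000, 1700), base)
    # halving length doubles RPKM
    assert np.isclose(cluster_rpkm(57, 3_000_000, 850), 2 * base)
    with pytest.raises(ValueError):
        cluster_rpkm(1, 0, 100)


def test_directionality_labels():
    assert directionality(10, 0) == ("unidirectional+", 1.0)
    assert directionality(0, 10)[0] == "unidirectional-"
    assert directionality(5, 5)[0] == "bidirectional"
    assert directionality(8, 2)[0] == "unidirectional+"  # 0.8 threshold inclusive
    with pytest.raises(ValueError):
        directionality(0, 0)


def test_sensitivity_grid_monotone(rng):
    intervals = [(int(s), int(s) + 28) for s in rng.integers(0, 30000, size=500)]
    m = _mappings(intervals)
    grid = sensitivity_grid(m, distances=[0, 100, 1000, 10 ** 9], coverages=[1, 2, 6, 10])
    assert (np.diff(grid.to_numpy(), axis=1) <= 0).all()
    # d=inf, c=1 -> one cluster per scaffold bearing >=1 hit
    assert grid.loc[10 ** 9, 1] == 1
    # every cell equals direct recomputation
    for d in (100, 1000):
        for c in (2, 6):
            assert grid.loc[d, c] == len(call_clusters(m, d, c))


def test_dot_matrix_diagonal_symmetry_and_tandem():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    dots = dot_matrix(seq, word=10)
    n = len(seq) - 10 + 1
    assert {(i, i) for i in range(n)} <= dots
    assert all((j, i) in dots for i, j in dots)
    unit = "".join(rng.choice(list("ACGT"), size=25))
    dots2 = dot_matrix(unit * 2, word=10)
    off = [(i, j) for i, j in dots2 if j - i == 25]
    assert len(off) == 25 - 10 + 1  # full off-diagonal run at the unit offset
    with pytest.raises(ValueError):
        dot_matrix("ACGT", word=10)


def test_reciprocal_overlap_scoring():
    from pirnascape.types import Cluster

    truth = pd.DataFrame({"scaffold": ["s1", "s1"], "start": [0, 5000],
                          "end": [1000, 6000]})
    called = [Cluster("a", "s1", 10, 990), Cluster("b", "s1", 8000, 9000)]
    score = reciprocal_overlap_match(called, truth)
    assert score["recall"] == 0.5 and score["precision"] == 0.5
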