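"""Step 4: piRNA selection, unique-sequence collapse, RPM, 5' composition."""

import numpy as np
import pytest

from pirnascape._seq import phred_to_string
from pirnascape.pirnaselect import (add_rpm, base_composition, collapse_unique,
                                    compute_rpm, five_prime_u_fraction,
                                    locus_distribution, select_pirnas)
from pirnascape.types import MappingRecord, SmallRNARead, UniqueSequenceRecord


def _read(seq, rid="r", lib="L"):
    return SmallRNARead(rid, seq, phred_to_string(np.full(len(seq), 30)), lib)


def _rec(seq, counts, loci_spec):
    loci = [MappingRecord("", scaf, s, s + len(seq), strand, 0)
            for scaf, s, strand in loci_spec]
    return UniqueSequenceRecord(sequence=seq, counts=counts, loci=loci)


def test_size_selection_boundaries(rng):
    reads = [_read("A" * L, rid=f"r{L}_{i}")
             for i, L in enumerate([25, 26, 31, 32, 28, 15])]
    kept = select_pirnas(reads)
    assert sorted(len(r.sequence) for r in kept) == [26, 28, 31]
    lengths = [int(rng.integers(15, 40)) for _ in range(500)]
    mixed = [_read("C" * L, rid=f"m{i}") for i, L in enumerate(lengths)]
    assert len(select_pirnas(mixed)) == sum(1 for L in lengths if 26 <= L <= 31)


def test_collapse_counts_and_conservation(rng):
    seqs = ["ACGTACGTACGTACGTACGTACGTACGTA",
            "TTGCATTGCATTGCATTGCATTGCATTGC"]
    hit_lists = {s: [MappingRecord("", "s1", 0, len(s), "+", 0)] for s in seqs}
    reads = [_read(seqs[0], f"a{i}", "lib1") for i in range(5)]
    reads += [_read(seqs[0], f"b{i}", "lib2") for i in range(3)]
    reads += [_read(seqs[1], f"c{i}", "lib2") for i in range(2)]
    recs = collapse_unique(reads, hit_lists)
    by_seq = {u.sequence: u for u in recs}
    assert by_seq[seqs[0]].counts == {"lib1": 5, "lib2": 3}
    assert by_seq[seqs[1]].counts == {"lib2": 2}
    assert sum(u.total_count for u in recs) == len(reads)
    # random multiset conservation
    pool = [seqs[i % 2] + "" for i in range(200)]
    reads = [_read(pool[int(rng.integers(len(pool)))], f"x{i}") for i in range(300)]
    recs = collapse_unique(reads, hit_lists)
    assert sum(u.total_count for u in recs) == 300


def test_collapse_missing_hit_list_is_contract_violation():
    with pytest.raises(RuntimeError, match="contract"):
        collapse_unique([_read("ACGTACGTACGTACGTACGTACGTAC")], {})


def test_rpm_definition_and_normalization():
    assert compute_rpm(5, 10 ** 6) == 5.0
    assert compute_rpm(1234, 1234) == 1e6
    with pytest.raises(ValueError):
        compute_rpm(1, 0)
    recs = [_rec("A" * 28, {"L": c}, [("s1", i * 100, "+")])
            for i, c in enumerate([5, 10, 85])]
    add_rpm(recs)
    assert np.isclose(sum(u.rpm["L"] for u in recs), 1e6, rtol=1e-9)


def test_base_composition_rows_sum_to_one():
    recs = [_rec("TACGTACGTACGTACGTACGTACGTACG", {"L": 3}, [("s1", 0, "+")]),
            _rec("ATGCATGCATGCATGCATGCATGCATGC", {"L": 1}, [("s1", 50, "+")])]
    comp = base_composition(recs, n_positions=10)
    assert np.allclose(comp.sum(axis=1), 1.0)
    assert comp.loc[1, "T"] == 0.5  # unweighted: one of two sequences
    weighted = base_composition(recs, n_positions=1, weighted=True)
    assert weighted.loc[1, "T"] == 0.75  # 3 of 4 reads
    only_t = [_rec("TTTTTTTTTTTTTTTTTTTTTTTTTTTT", {"L": 1}, [("s1", 0, "+")])]
    assert five_prime_u_fraction(only_t) == 1.0


def test_equal_weight_two_records_split_position_one():
    recs = [_rec("A" * 28, {"L": 1}, [("s1", 0, "+")]),
            _rec("C" * 28, {"L": 1}, [("s1", 100, "+")])]
    comp = base_composition(recs, n_positions=1)
    assert comp.loc[1, "A"] == 0.5 and comp.loc[1, "C"] == 0.5


def test_locus_classification_partition():
    u1 = _rec("A" * 28, {"L": 2}, [("s1", 0, "+")])
    multi = _rec("C" * 28, {"L": 2}, [("s1", 0, "+"), ("s2", 10, "+")])
    tandem = _rec("G" * 28, {"L": 2}, [("s1", 0, "+"), ("s1", 300, "+"),
                                       ("s1", 600, "-")])
    assert u1.locus_class == "unique-locus"
    assert multi.locus_class == "multi-locus"
    assert tandem.locus_class == "multi-tandem"
    hist, fracs = locus_distribution([u1, multi, tandem])
    assert hist.to_dict() == {1: 1, 2: 1, 3: 1}
    assert np.isclose(sum(fracs.values()), 1.0)
    # reads > 1 display filter
    low = _rec("T" * 28, {"L": 1}, [("s1", 900, "+")])
    _, fr = locus_distribution([u1, multi, tandem, low], min_reads=1)
    assert np.isclose(sum(fr.values()), 1.0)


def test_planted_tandem_reads_classified_multi_tandem(small_run):
    """Error-free reads wholly inside one unit of a planted tandem array
    carry that sequence at every copy, hence class multi-tandem."""
    res = small_run
    truth = res.truth
    tandem_ids = set(res.genome.clusters[res.genome.clusters["tandem"]]["cluster_id"])
    if not tandem_ids:
        pytest.skip("no tandem clusters in this configuration")
    tr = truth[(truth["true_class"] == "pirna_like") & (truth["n_errors"] == 0)
               & truth["cluster_id"].isin(tandem_ids)]
    seq_class = {u.sequence: u.locus_class for u in res.unique_records}
    rows = res.genome.clusters.set_index("cluster_id")
    n_checked = n_tandem = 0
    for t in tr.itertuples(index=False):
        row = rows.loc[int(t.cluster_id)]
        offset = int(t.start) - int(row["start"])
        unit = int(row["unit_length"])
        if offset % unit > unit - int(t.length):
            continue  # straddles a unit boundary
        # find the unique record carrying this read's sequence
        scaffold_seq = res.genome.scaffolds[t.scaffold]
        insert = scaffold_seq[int(t.start): int(t.end)]
        if t.strand == "-":
            from pirnascape._seq import revcomp
            insert = revcomp(insert)
        if insert in seq_class:
            n_checked += 1
            n_tandem += seq_class[insert] == "multi-tandem"
        if n_checked >= 50:
            break
    assert n_checked > 0
    assert n_tandem == n_checked
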