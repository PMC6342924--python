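"""Simulator: determinism, planted architecture, and read statistics."""

import numpy as np
import pandas as pd
import pytest

from pirnascape._seq import revcomp
from pirnascape.simulate import (GenomeConfig, SimulationError,
                                 default_study_profiles, generate_genome,
                                 simulate_library)

from _oracles import exhaustive_hits


def test_genome_deterministic_and_empty_cluster_case():
    cfg = GenomeConfig(n_scaffolds=3, scaffold_length=8000, n_clusters=0, seed=9)
    g1 = generate_genome(cfg)
    g2 = generate_genome(cfg)
    assert g1.scaffolds == g2.scaffolds
    assert len(g1.clusters) == 0
    cfg2 = GenomeConfig(n_scaffolds=2, scaffold_length=20_000, n_clusters=4, seed=9)
    assert generate_genome(cfg2).clusters.equals(generate_genome(cfg2).clusters)


def test_cluster_intervals_disjoint_within_bounds(small_genome):
    cl = small_genome.clusters
    for scaffold, sub in cl.groupby("scaffold"):
        sub = sub.sort_values("start")
        assert (sub["start"] >= 0).all()
        assert (sub["end"] <= len(small_genome.scaffolds[scaffold])).all()
        gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
        assert (gaps > small_genome.config.min_cluster_gap).all()


def test_tandem_clusters_contain_exact_unit_copies():
    """With frac_tandem=1 and fixed copy number, every cluster's unit occurs
    at least that many times on its scaffold (substring-count oracle)."""
    cfg = GenomeConfig(n_scaffolds=2, scaffold_length=30_000, n_clusters=6,
                       frac_tandem=1.0, tandem_unit_length=200,
                       tandem_copy_range=(3, 3), seed=4)
    g = generate_genome(cfg)
    for _, row in g.clusters.iterrows():
        seq = g.scaffolds[row["scaffold"]]
        unit = seq[row["start"]: row["start"] + row["unit_length"]]
        count = sum(1 for i in range(len(seq) - len(unit) + 1)
                    if seq[i: i + len(unit)] == unit)
        assert row["tandem"] and count >= 3


def test_infeasible_packing_raises():
    cfg = GenomeConfig(n_scaffolds=1, scaffold_length=5000, n_clusters=10,
                       cluster_length_range=(2000, 2000), seed=0)
    with pytest.raises(SimulationError, match="infeasible packing"):
        generate_genome(cfg)


def test_empty_library_and_determinism(small_genome):
    profile = default_study_profiles(n_reads=0, seed=3)[0]
    reads, truth = simulate_library(small_genome, profile)
    assert reads == [] and len(truth) == 0
    profile = default_study_profiles(n_reads=3000, seed=3)[1]
    reads_a, truth_a = simulate_library(small_genome, profile)
    reads_b, truth_b = simulate_library(small_genome, profile)
    assert [(a.id, a.sequence, a.qualities) for a in reads_a] == \
           [(b.id, b.sequence, b.qualities) for b in reads_b]
    pd.testing.assert_frame_equal(truth_a, truth_b)


def test_class_mix_within_multinomial_noise(small_library):
    profile, _, truth = small_library
    n = len(truth)
    for cls, frac in profile.class_mix.items():
        got = (truth["true_class"] == cls).sum()
        sd = np.sqrt(n * frac * (1 - frac))
        assert abs(got - n * frac) <= 3 * sd + 1


def test_somatic_length_bimodality(small_library):
    _, _, truth = small_library
    frac_mi = truth["length"].between(21, 23).mean()
    frac_pi = truth["length"].between(29, 31).mean()
    assert frac_mi > 0.10 and frac_pi > 0.30


def test_gonadal_single_peak(small_genome):
    profile = default_study_profiles(n_reads=20_000, seed=8)[3]
    assert profile.tissue_class == "gonadal"
    _, truth = simulate_library(small_genome, profile)
    assert truth["length"].between(21, 23).mean() <= 0.05


def test_u1_fraction_matches_configuration(small_genome):
    profile = default_study_profiles(n_reads=20_000, u1_prob=0.85, seed=21)[0]
    _, truth = simulate_library(small_genome, profile)
    pir = truth[truth["true_class"] == "pirna_like"]
    p = 0.85
    sd = np.sqrt(p * (1 - p) / len(pir))
    # sequencing errors can flip the 5' base at ~error_rate
    assert abs(pir["five_prime_t"].mean() - p) <= 3 * sd + 2 * profile.error_rate


def test_error_free_pirna_reads_align_to_planted_clusters(small_genome, small_library):
    """Every error-free piRNA-like read matches its truth interval exactly
    and maps inside a planted cluster (brute-force check on a sample)."""
    _, reads, truth = small_library
    by_id = {r.id: r for r in reads}
    pir = truth[(truth["true_class"] == "pirna_like") & (truth["n_errors"] == 0)]
    cl = small_genome.clusters
    for row in pir.head(80).itertuples(index=False):
        insert = by_id[row.read_id].sequence[: row.length]
        genomic = small_genome.scaffolds[row.scaffold][int(row.start): int(row.end)]
        assert insert == (genomic if row.strand == "+" else revcomp(genomic))
        inside = cl[(cl["scaffold"] == row.scaffold)
                    & (cl["start"] <= int(row.start))
                    & (cl["end"] >= int(row.end))]
        assert len(inside) == 1
    # spot-check with the exhaustive mapper oracle on one scaffold
    sample = pir[pir["scaffold"] == pir.iloc[0]["scaffold"]].head(5)
    sub = {s: small_genome.scaffolds[s] for s in [sample.iloc[0]["scaffold"]]}
    for row in sample.itertuples(index=False):
        insert = by_id[row.read_id].sequence[: row.length]
        assert len(exhaustive_hits(insert, sub, max_mm=0)) >= 1
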