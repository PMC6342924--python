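"""End-to-end workflow: simulate → Step 1–4 → clusters → differential
expression, with a per-library attrition report.

A single global seed fans out deterministically to the genome and each
library via :class:`numpy.random.SeedSequence`, so a rerun with the same
configuration is byte-identical. Default thresholds are the analysis
defaults used throughout the package (mean Q > 20, 15–35 nt, ≤1
mismatch, 26–31 nt, merge ≤ 1 kb, coverage ≥ 6, FDR < 0.01,
|log2 ratio| > 1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotfilter, clustercall, diffexpr, io, mapper, pirnaselect, readproc
from .simulate import (DEFAULT_ADAPTER, GenomeConfig, LibraryProfile,
                       SyntheticGenome, default_study_profiles, generate_genome,
                       simulate_library)
from .types import Cluster, StepCounts


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place; defaults are the standard run."""

    outdir: str | None = None
    seed: int = 0
    # simulation
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    n_reads_per_library: int = 200_000
    u1_prob: float = 0.8
    profiles: list[LibraryProfile] | None = None  # override the default design
    # step 1
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 3
    min_mean_quality: float = 20.0
    length_range: tuple[int, int] = (15, 35)
    # step 2
    known_k: int = 7
    known_max_mismatch: int = 1
    # step 3
    genome_k: int = 12
    max_mismatch: int = 1
    # step 4
    size_range: tuple[int, int] = (26, 31)
    # clusters
    merge_distance: int = 1000
    min_coverage: int = 6
    direction_threshold: float = 0.8
    count_multimaps: bool = True
    # differential expression
    fdr: float = 0.01
    min_abs_log2: float = 1.0
    groups: dict[str, str] | None = None
    write_intermediate: bool = True


@dataclass
class PipelineResult:
    """Everything the run produced, in memory."""

    config: PipelineConfig
    genome: SyntheticGenome
    truth: pd.DataFrame
    step_counts: StepCounts
    removed_known: dict[str, dict[str, int]]
    unique_records: list
    library_totals: dict[str, int]
    mappings: pd.DataFrame  # placements of selected piRNA reads
    clusters: list[Cluster]
    matrix: diffexpr.ExpressionMatrix | None
    venn: dict | None
    pca: pd.DataFrame | None
    de_results: dict[str, pd.DataFrame]
    recovery: dict | None
    report: dict
    checksums: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full simulated study through the analysis pipeline."""
    root = np.random.SeedSequence(config.seed)
    genome_seed, profile_seed = (int(s) for s in root.generate_state(2) % (2 ** 31))
    genome = generate_genome(dataclasses.replace(config.genome, seed=genome_seed))
    profiles = config.profiles if config.profiles is not None else \
        default_study_profiles(config.n_reads_per_library, config.u1_prob,
                               seed=profile_seed)

    outdir = config.outdir
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    known_index = annotfilter.build_known_index(genome.known_rna, k=config.known_k)
    genome_index = mapper.build_genome_index(genome.scaffolds, k=config.genome_k)

    step_counts = StepCounts()
    removed_known: dict[str, dict[str, int]] = {}
    hit_cache: dict = {}
    truths = []
    pirna_reads_all = []
    hit_tables = []

    for profile in profiles:
        lib = profile.name
        reads, truth = simulate_library(genome, profile)
        truths.append(truth)
        if outdir and config.write_intermediate:
            io.write_fastq(os.path.join(outdir, f"{lib}.fastq"), reads)

        s1 = readproc.process_library(
            reads, config.adapter, config.min_overlap, config.min_mean_quality,
            config.length_range, step_counts=step_counts, library=lib)
        del reads

        s2, removed = annotfilter.subtract_known(
            s1, known_index, config.known_max_mismatch)
        removed_known[lib] = removed
        step_counts.record(lib, "step2", len(s2))
        for cls, n in removed.items():
            step_counts.record_removed(lib, f"step2_{cls}", n)
        del s1

        table, mapped = mapper.map_library(
            s2, genome_index, config.max_mismatch, step_counts=step_counts,
            library=lib, hit_cache=hit_cache)
        del s2

        pirnas = pirnaselect.select_pirnas(
            mapped, config.size_range, step_counts=step_counts, library=lib)
        del mapped
        lo, hi = config.size_range
        span = table["end"] - table["start"]
        hit_tables.append(table[(span >= lo) & (span <= hi)])
        pirna_reads_all.extend(pirnas)

    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    mappings = (pd.concat(hit_tables, ignore_index=True)
                if hit_tables else pd.DataFrame(columns=mapper._HIT_COLUMNS))

    library_totals = {p.name: step_counts.get(p.name, "step4") for p in profiles}

    hit_lists = {}
    for r in pirna_reads_all:
        if r.sequence not in hit_lists:
            hit_lists[r.sequence] = mapper.lite_hits_to_records(
                r.sequence, hit_cache[r.sequence], genome_index)
    unique_records = pirnaselect.collapse_unique(pirna_reads_all, hit_lists)
    pirnaselect.add_rpm(unique_records, library_totals)

    clusters = clustercall.call_clusters(
        mappings, config.merge_distance, config.min_coverage,
        library_totals={k: v for k, v in library_totals.items() if v > 0},
        direction_threshold=config.direction_threshold,
        count_multimaps=config.count_multimaps)

    matrix = venn = pca = None
    de_results: dict[str, pd.DataFrame] = {}
    groups = config.groups
    if groups is None:
        groups = {p.name: p.name[:-1] if p.name[-1].isdigit() else p.name
                  for p in profiles}
    if clusters and all(v > 0 for v in library_totals.values()):
        matrix = diffexpr.build_matrix(clusters, library_totals, groups)
        venn = diffexpr.presence_overlap(matrix)
        try:
            pca = diffexpr.pca_scores(matrix)
        except ValueError:
            pca = None
        tissue_class: dict[str, str] = {}
        for p in profiles:
            tissue_class.setdefault(groups.get(p.name, ""), p.tissue_class)
        gonadal = [t for t in matrix.tissues if tissue_class.get(t) == "gonadal"]
        somatic = [t for t in matrix.tissues if tissue_class.get(t) == "somatic"]
        for ta in somatic:
            for tb in gonadal:
                res = diffexpr.differential_test(
                    matrix, ta, tb, config.fdr, config.min_abs_log2)
                de_results[f"{ta}_vs_{tb}"] = diffexpr.results_table(res)

    recovery = None
    if len(genome.clusters):
        recovery = clustercall.reciprocal_overlap_match(clusters, genome.clusters)

    report = _build_report(config, step_counts, removed_known, clusters,
                           venn, de_results, recovery, library_totals,
                           unique_records)
    checksums: dict[str, str] = {}
    if outdir:
        checksums = _write_outputs(outdir, config, genome, truth, step_counts,
                                   unique_records, clusters, matrix, pca,
                                   de_results, mappings, report)
        report["checksums"] = checksums
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)

    return PipelineResult(
        config=config, genome=genome, truth=truth, step_counts=step_counts,
        removed_known=removed_known, unique_records=unique_records,
        library_totals=library_totals, mappings=mappings, clusters=clusters,
        matrix=matrix, venn=venn, pca=pca, de_results=de_results,
        recovery=recovery, report=report, checksums=checksums)


def _build_report(config, step_counts, removed_known, clusters, venn,
                  de_results, recovery, library_totals, unique_records):
    hist, fractions = pirnaselect.locus_distribution(unique_records)
    u1 = pirnaselect.five_prime_u_fraction(unique_records)
    u1_weighted = pirnaselect.five_prime_u_fraction(unique_records, weighted=True)
    report = {
        "parameters": {
            "seed": config.seed,
            "n_reads_per_library": config.n_reads_per_library,
            "min_mean_quality": config.min_mean_quality,
            "length_range": list(config.length_range),
            "max_mismatch": config.max_mismatch,
            "size_range": list(config.size_range),
            "merge_distance": config.merge_distance,
            "min_coverage": config.min_coverage,
            "fdr": config.fdr,
            "min_abs_log2": config.min_abs_log2,
        },
        "step_counts": {lib: dict(row) for lib, row in step_counts.counts.items()},
        "removed": {lib: dict(row) for lib, row in step_counts.removed.items()},
        "accounted": {lib: step_counts.accounted(lib)
                      for lib in step_counts.counts},
        "library_totals": library_totals,
        "n_unique_sequences": len(unique_records),
        "five_prime_u_unique": u1,
        "five_prime_u_weighted": u1_weighted,
        "locus_class_fractions": fractions,
        "n_clusters": len(clusters),
        "frac_clusters_gt_1kb": (
            float(np.mean([c.length > 1000 for c in clusters])) if clusters else 0.0),
        "n_significant": {cmp: int(df["significant"].sum())
                          for cmp, df in de_results.items()},
    }
    if venn is not None:
        report["venn"] = {"+".join(sorted(k)) if k else "none": v
                          for k, v in venn.items()}
    if recovery is not None:
        report["recovery"] = {k: v for k, v in recovery.items() if k != "pairs"}
    return report


def _write_outputs(outdir, config, genome, truth, step_counts, unique_records,
                   clusters, matrix, pca, de_results, mappings, report):
    libs = sorted(step_counts.counts)
    paths = []

    def path(name):
        p = os.path.join(outdir, name)
        paths.append(p)
        return p

    io.write_fasta(path("genome.fa"), genome.scaffolds.items())
    for cls, refs in genome.known_rna.items():
        if refs:
            io.write_fasta(path(f"known_{cls}.fa"), refs)
    io.write_bed6(path("planted_clusters.bed"), (
        (r.scaffold, int(r.start), int(r.end), f"planted{int(r.cluster_id)}",
         0, {"unidirectional+": "+", "unidirectional-": "-"}.get(r.strand_mode, "."))
        for r in genome.clusters.itertuples(index=False)))
    if config.write_intermediate and len(truth):
        truth.to_csv(path("truth_reads.tsv"), sep="\t", index=False)
    step_counts.as_table().to_csv(path("step_counts.tsv"), sep="\t")
    clustercall.clusters_table(clusters, libs).to_csv(
        path("clusters.tsv"), sep="\t", index=False)
    io.write_bed6(path("clusters.bed"), clustercall.clusters_to_bed(clusters))
    if config.write_intermediate:
        pirnaselect.unique_table(unique_records, libs).to_csv(
            path("unique_sequences.tsv"), sep="\t", index=False)
        io.write_bedgraph(path("pirna_coverage.bedgraph"),
                          clustercall.coverage_bedgraph(mappings),
                          track_name="piRNA coverage")
    if pca is not None:
        pca.to_csv(path("pca_scores.tsv"), sep="\t")
    for cmp, df in de_results.items():
        df.to_csv(path(f"de_{cmp}.tsv"), sep="\t", index=False)

    checksums = {}
    for p in paths:
        with open(p, "rb") as fh:
            checksums[os.path.basename(p)] = hashlib.md5(fh.read()).hexdigest()
    return checksums


def embedded_sequence_cluster_span(
    sequence: str,
    n_reads: int = 6,
    merge_distance: int = 1000,
    min_coverage: int = 6,
    scaffold_length: int = 2000,
    seed: int = 0,
) -> int:
    """Span (bp) of the cluster called from ``n_reads`` identical copies of
    one sequence planted once in a random scaffold.

    The sequence is embedded at a fixed locus, the identical reads are
    mapped all-hits with ≤1 mismatch and clusters are called with the
    given merge distance and coverage floor; the single resulting
    cluster's end − start is returned.
    """
    from ._seq import random_dna

    rng = np.random.default_rng(seed)
    insert_at = scaffold_length // 2
    backbone = random_dna(rng, scaffold_length)
    scaffold = (backbone[:insert_at] + sequence.upper()
                + backbone[insert_at + len(sequence):])
    index = mapper.build_genome_index({"scaffold1": scaffold})
    rows = {c: [] for c in mapper._HIT_COLUMNS}
    for i in range(n_reads):
        for rec in mapper.map_read(sequence.upper(), index):
            rows["read_id"].append(f"r{i + 1}")
            rows["library"].append("demo")
            rows["scaffold"].append(rec.scaffold)
            rows["start"].append(rec.start)
            rows["end"].append(rec.end)
            rows["strand"].append(rec.strand)
            rows["mismatches"].append(rec.mismatches)
    mappings = pd.DataFrame(rows)
    clusters = clustercall.call_clusters(mappings, merge_distance, min_coverage)
    if len(clusters) != 1:
        raise RuntimeError(f"expected exactly one cluster, got {len(clusters)}")
    return clusters[0].length
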