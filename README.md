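# pirnascape

Putative piRNA discovery and characterisation from small RNA-seq, built
for fragmented (scaffold-level) genome assemblies such as the pearl
oyster's, where piRNAs are abundant not only in the gonad but across
somatic tissues.

Piwi-interacting RNAs (piRNAs) are 26–31 nt small RNAs with a strong 5′
uridine bias, transcribed from genomic *piRNA clusters* and often laid
out in tandem repeats. Starting from raw FASTQ libraries, the pipeline:

1. **Step 1 — read processing**: 3′-adapter trimming, removal of reads
   with mean Phred ≤ 20, reads containing N, and reads outside 15–35 nt.
2. **Step 2 — known-RNA subtraction**: removal of reads contained
   end-to-end (either strand, ≤1 substitution) in user-supplied
   miRNA/rRNA/tRNA/snRNA/snoRNA reference sets.
3. **Step 3 — all-hits mapping**: every genome placement with ≤1
   substitution on either strand (pigeonhole-seeded k-mer index; no
   indels, no hit cap — multi-mapping is the signal, not noise).
4. **Step 4 — piRNA selection**: mapped reads of 26–31 nt, collapsed to
   unique sequences with per-library counts and
   RPM = count / (library piRNA total) × 10⁶, 5′-base composition, and
   the unique-/multi-locus/multi-tandem placement partition.
5. **Cluster calling**: strand-agnostic single-linkage merging of
   mapping loci (gap ≤ 1 kb), a pooled coverage floor of 6 placements,
   cluster naming in scaffold order, directionality labels
   (≥80 % of hits on one strand → unidirectional), and genomic-length
   RPKM = reads × 10⁶ / (library piRNA total × cluster length in kb).
6. **Differential cluster expression**: presence overlaps across
   tissues (Venn), PCA of log₂(RPKM+1), and per-cluster two-sided
   Fisher exact tests on pooled tissue counts with Benjamini–Hochberg
   FDR; a cluster is differential at FDR < 0.01 and |log₂ ratio| > 1.

Because real libraries of this depth are impractical for routine
verification, the package ships a first-class **synthetic study
generator** (`pirnascape.simulate`) that plants the complete ground
truth: a multi-scaffold genome with disjoint piRNA clusters
(unidirectional/bidirectional, a fraction as exact tandem arrays),
known-RNA references, and eight tissue libraries (two replicates each of
mantle Ma, adductor muscle Ad, gill Gi, gonad Go) with bimodal
(somatic) or unimodal (gonadal) length distributions, a configurable 5′U
rate, substitution sequencing errors, contaminant and noise reads — plus
truth tables for every read and cluster, so recovery can be scored.

## Worked example

Run the standard simulated study (8 × 200,000 reads, 1 Mb genome, 100
planted clusters) end to end:

```
pirnascape run --outdir out --seed 3
```

which prints the per-library attrition table and summary (abridged):

```
       raw   step1   step2   step3   step4
Ma1  200000  195256  107790   88233   88125
...
Go2  200000  195329  165849  146017  145895
100 clusters called; report in out/report.json
```

Reading `out/report.json` from that run: Step 2 removes roughly half of
each somatic library (the 21–23 nt miRNA-like peak plus known-RNA
fragments) but much less of the gonadal libraries, which lack that peak;
312,909 unique piRNA sequences remain, of which 87.6 % map to a single
locus and 12.4 % map multi-tandem (≥2 placements on one scaffold, the
signature of tandem-array clusters); the read-weighted 5′U fraction is
0.798 against a configured bias of 0.80. All 100 planted clusters are
recovered at 50 % reciprocal overlap (recall = precision = 1.0); 85 are
expressed in all four tissues and 15 only in gonad (exactly the planted
gonad-specific set), and 18 clusters per somatic–gonadal comparison pass
FDR < 0.01 with |log₂ ratio| > 1.

Library API equivalent: `pirnascape.pipeline.run_pipeline(PipelineConfig(...))`
returns all of the above as in-memory objects (`StepCounts`, `Cluster`
lists, expression matrices, DE tables, truth tables).

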