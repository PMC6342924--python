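# Methods

## Scope and model

The pipeline identifies putative piRNAs from single-end small RNA-seq by
a four-step filtering cascade, then calls piRNA clusters from mapping
density and compares cluster expression between somatic and gonadal
tissues. It assumes: reads are short (≤35 nt) single-end fragments with
a ligated 3′ adapter; piRNAs are 26–31 nt, genome-encoded, and may
legitimately map to many loci (tandem arrays); a fragmented assembly, so
all coordinates are per-scaffold; and no piRNA precursor annotation, so
cluster expression is normalised by *genomic* interval length rather
than transcript length.

## Filtering cascade

* **Adapter trimming** removes the longest read suffix equal to a prefix
  of the adapter, requiring ≥3 exactly matching bases (configurable).
  This recovers the insert exactly whenever the full adapter is present
  and degrades gracefully to a no-op.
* **Step 1** keeps reads with arithmetic mean Phred strictly greater
  than 20 (a mean of exactly 20.0 is removed), no N, and trimmed length
  in [15, 35]. The mean is computed on the trimmed read.
* **Step 2** removes a read iff it lies end-to-end within a known-RNA
  reference (either strand) with ≤1 substitution. This is a defined,
  deterministic stand-in for a database screen; the threshold is
  configurable. When a read matches several classes it is attributed to
  the first of miRNA, rRNA, tRNA, snRNA, snoRNA — the order biases
  per-class removal counts but never the surviving read set.
* **Step 3** reports *all* placements with Hamming distance ≤1 on both
  strands, no indels and no hit cap. Capping would truncate the
  multi-mapping (tandem) tail that the locus-distribution analysis
  measures.
* **Step 4** keeps mapped reads of 26–31 nt as putative piRNAs.

## Mapper

Completeness rests on the pigeonhole principle: with one mismatch
allowed, one of two disjoint k-mer seeds must be exact. Two seed sizes
are indexed over the same genome (k = 12 for reads ≥ 24 nt, k = 7 for
14–23 nt; below 14 nt every offset is seeded, which is complete only
for ≤1 mismatch when the read still contains an exact 7-mer — reads
that short are outside the Step-1 window anyway). Scaffolds are
concatenated with 36 pad bytes that mismatch every base, so candidate
verification is one vectorised window comparison; verified hits are
bounds-checked against the owning scaffold. N (in read or genome)
matches nothing. The mapper is checked exactly against an exhaustive
sliding-window Hamming oracle in the test suite, at both mismatch
settings.

The same Step-3 hit table feeds cluster calling; no re-mapping with a
second aligner is performed, keeping one mapping semantics throughout.

## Cluster calling

Loci are merged per scaffold by single linkage with the rule *gap ≤
merge distance merges* (so two 30 bp hits whose gap is exactly 1000 bp
form one region at the default d = 1000; this matches the common
merge-tool convention for `-d`). Regions with pooled coverage ≥6
placements become clusters; coverage counts every placement of a
multi-mapped read (a count-once-per-read mode exists behind a flag),
pooled across all libraries, so one cluster set serves all tissues and
per-tissue presence is simply ≥1 overlapping read. Clusters are named
`<scaffold>.cl<n>` in coordinate order. Directionality uses a 0.8
plus-fraction threshold (inclusive); the dichotomy is visually obvious
in real data but not quantified anywhere authoritative, so 0.8 is this
package's choice, configurable. A sensitivity grid recomputes cluster
counts over merge-distance × coverage combinations; counts are
non-increasing in the coverage floor at fixed distance.

"Multi-tandem" for a unique sequence means ≥2 placements on a single
scaffold, with no spacing or strand constraint — no distance criterion
is defensible without a repeat annotation. Locus-class statistics are
computed over unique sequences, with an optional reads-weighted mode,
since the two conventions genuinely differ and published figures are
ambiguous between them.

## Differential expression

Replicates are pooled per tissue: with n = 2 per tissue, a
negative-binomial dispersion estimate would be unstable, and the pooled
Fisher exact test on (cluster reads vs all-other-cluster reads) ×
(tissue A vs tissue B) is fully specified and exactly testable against
a hypergeometric-sum oracle. Benjamini–Hochberg FDR runs across
clusters within a comparison (statsmodels' implementation, verified
against the textbook step-up form). The effect size is
log₂((RPKM_A + ε)/(RPKM_B + ε)) on pooled-tissue RPKM with ε = 0.01
RPKM to stabilise ratios at zero counts; significance requires FDR <
0.01 *and* |log₂ ratio| > 1. Consequences of pooling: no within-tissue
variance model, so p-values are calibrated against the no-difference
null (verified by simulation: mean fraction of clusters at FDR < 0.01
is ≤ 0.01 over 20 null studies) but will be anti-conservative under
strong biological replicate dispersion — counts-based claims on real
data should treat the FDR as descriptive. PCA operates on
log₂(RPKM + 1) with libraries as observations and constant clusters
dropped.

## Synthetic study generator

The generator emulates the statistical structure the analysis relies
on, with planted truth for every read and cluster:

* **Genome**: 20 scaffolds × 50 kb (1 Mb) by default, uniform random
  sequence; 100 planted clusters of 500–3000 bp, pairwise separated by
  >2.5 kb so the 1 kb merge cannot fuse neighbours; 25 % of clusters
  are tandem arrays of an exact 300 bp unit (3–6 copies; array length
  then overrides the length range); 30 % of clusters are bidirectional,
  the rest unidirectional with a random sign. Cluster expression
  weights are log-normal (σ = 1); 15 % of clusters get zero somatic
  weight (gonad-specific), giving the DE stage a planted signal.
  Known-RNA references (24 nt miRNAs; longer rRNA/tRNA/snRNA/snoRNA)
  are drawn independently and re-drawn if they share any 26-mer with a
  planted cluster, so Step 2 cannot remove genuine piRNA reads.
* **Libraries**: eight libraries, 2×10⁵ reads each by default — two
  replicates of each of mantle/adductor/gill (somatic: 45 % piRNA-like,
  25 % miRNA-like, 20 % known-RNA, 10 % noise) and gonad (75/0/15/10).
  piRNA-like lengths peak at 29–31 nt, miRNA-like at 21–23 nt, so
  somatic libraries are bimodal and gonadal unimodal. These mixture
  magnitudes are free parameters of the generator chosen to look like
  a typical deep somatic small-RNA library; they are not calibrated to
  any particular deposited dataset.
* **piRNA-like reads** are exact substrings of planted cluster
  intervals on the planted strand(s). The 5′ base is T with probability
  `u1_prob` (default 0.8) *exactly*: a Bernoulli draw selects the target
  5′ base and the start site is sampled uniformly among positions whose
  genomic base realises it — the genome is never edited. Sampling the
  non-T branch explicitly (rather than unconstrained) is what makes the
  read-level 5′U rate equal the parameter, so parameter recovery is a
  well-posed binomial check.
* **miRNA-like reads** are 5′-anchored fragments of miRNA references;
  known-RNA reads are random fragments (16–34 nt, either strand) of the
  other reference classes; both are removed by Step 2 up to injected
  errors. Noise reads are uniform random 15–35-mers that mostly fail
  Step 3, producing the mapping-stage attrition.
* **Sequencing error** is a per-base substitution at rate 0.2 %
  (recorded per read in the truth table); qualities are per-read
  Gaussian means (30 ± 5) with per-base jitter, so ~2 % of reads fail
  the Step-1 quality floor. No indels and no position-dependent error
  profile are modelled; conclusions about indel robustness cannot be
  drawn from these tests.

Determinism: a single study seed fans out through
`numpy.random.SeedSequence` to the genome and each library; identical
seeds give byte-identical FASTQ output.

Because the observed 5′ base passes through the substitution channel,
the expected *observed* 5′T rate is u1(1−e) + (1−u1)e/3 (e = error
rate); the recovery test compares the pipeline's read-weighted estimate
to this forward-model value within 3 binomial SD. The unique-sequence-
weighted 5′U rate is systematically lower than the read-weighted one
(high-copy T-start sequences collapse to single records); both are
reported.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere, including BED/bedGraph
  output.
* RPM/RPKM raise on a zero library total rather than returning 0.
* `merge_loci` on an empty table returns an empty region set; a single
  hit yields a region equal to its span.
* Ties in greedy reciprocal-overlap matching (recovery scoring) break
  by larger overlap first; matching is one-to-one.
* Fisher tests run per cluster without continuity correction;
  two-sidedness follows the point-mass summation convention.

## Problem sizes used in the checks

The standard simulated study used by the deeper checks is 8 libraries ×
2×10⁵ reads on a 1 Mb genome with 100 planted clusters; oracle
equivalence for the mapper uses 20 genomes (≤20 kb) × 1000 reads, and
interval merging 200 random interval sets. These sizes make the brute-
force oracles exact re-computations rather than approximations.

## Known limitations

* No indel alignment (by contract) and no quality-aware mapping.
* Step 2 containment with a fixed mismatch budget is not equivalent to
  a heuristic database search with E-values; per-class removal counts
  are order-dependent.
* Pooled-count DE has no replicate dispersion model (see above).
* The simulator does not model ping-pong biogenesis signatures
  (10 nt 5′ overlaps), position-dependent error, or 3′ modification
  chemistry; tests passing here say nothing about those aspects of real
  data.
* `embedded_sequence_cluster_span` assumes the embedded sequence does
  not occur by chance elsewhere in the random scaffold (probability
  ≈ 2·10³·(1+3·30)/4³⁰ for a 30-mer in 2 kb; it raises if more than one
  cluster results).
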