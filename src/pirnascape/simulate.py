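"""Synthetic small RNA-seq study generator with planted ground truth.

Builds a multi-scaffold genome carrying planted piRNA clusters
(unidirectional or bidirectional; a configurable fraction laid out as
tandem arrays of an exact repeat unit) plus a set of known-RNA reference
sequences (miRNA/rRNA/tRNA/snRNA/snoRNA), then simulates per-tissue
FASTQ libraries whose statistical structure matches what the downstream
pipeline assumes:

* somatic libraries are bimodal in read length (a 21–23 nt miRNA-like
  peak and a 29–31 nt piRNA-like peak); gonadal libraries carry a single
  29–31 nt peak,
* piRNA-like reads are genomic substrings of planted clusters on the
  planted strand(s) with a configurable 5′-uridine bias (realised by
  start-site choice, never by editing the genome),
* known-RNA reads are fragments of the known-RNA references so the
  subtraction step has a truth, and noise reads are uniform random
  sequence that mostly fails genome mapping,
* every read and every planted cluster has a truth-table row.

Reads are stored DNA-alphabet (T not U); a 5′U is a 5′T on the read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import decode, encode, phred_to_string, random_dna, revcomp
from .types import SmallRNARead

__all__ = [
    "GenomeConfig",
    "LibraryProfile",
    "SyntheticGenome",
    "SimulationError",
    "generate_genome",
    "simulate_library",
    "simulate_study",
    "default_study_profiles",
    "DEFAULT_ADAPTER",
]

# Ion-style 3' adapter used when a profile does not override it.
DEFAULT_ADAPTER = "ATCACCGACTGCCCATAGAGAGG"

KNOWN_RNA_CLASSES = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA")

# Reference lengths per known-RNA class (mature miRNAs are kept at 24 nt so
# that 20-24 nt library fragments are always 5'-anchored sub-reads).
_KNOWN_LENGTHS = {"miRNA": 24, "rRNA": 400, "tRNA": 75, "snRNA": 120, "snoRNA": 100}
_KNOWN_SPLIT = {"miRNA": 0.40, "rRNA": 0.10, "tRNA": 0.25, "snRNA": 0.125, "snoRNA": 0.125}

READ_CLASSES = ("pirna_like", "mirna_like", "known_rna", "noise")


class SimulationError(ValueError):
    """Raised when a simulation configuration cannot be realised."""


@dataclass(frozen=True)
class GenomeConfig:
    """Architecture of the synthetic genome and its planted features.

    ``frac_gonad_specific`` controls how many planted clusters receive zero
    somatic expression weight, giving the differential-expression stage a
    planted signal. ``min_cluster_gap`` keeps planted clusters far enough
    apart that a 1 kb merge cannot fuse neighbours.
    """

    n_scaffolds: int = 20
    scaffold_length: int = 50_000
    n_clusters: int = 100
    cluster_length_range: tuple[int, int] = (500, 3000)
    frac_bidirectional: float = 0.3
    frac_tandem: float = 0.25
    tandem_unit_length: int = 300
    tandem_copy_range: tuple[int, int] = (3, 6)
    n_known_rna_loci: int = 40
    frac_gonad_specific: float = 0.15
    min_cluster_gap: int = 2500
    seed: int = 0


@dataclass(frozen=True)
class LibraryProfile:
    """Read-level composition of one simulated library.

    ``class_mix`` gives fractions over ``pirna_like``, ``mirna_like``,
    ``known_rna`` and ``noise`` (must sum to 1); gonadal profiles use a
    ``mirna_like`` fraction of 0, which yields the single 29–31 nt length
    peak. ``u1_prob`` is the probability that a piRNA-like read carries a
    5′U, realised exactly by start-site choice. ``cluster_weights``
    overrides the per-cluster expression weights from the genome truth
    table when given.
    """

    name: str
    tissue_class: str  # "somatic" | "gonadal"
    n_reads: int
    class_mix: dict[str, float]
    pirna_length_dist: dict[int, float]
    mirna_length_dist: dict[int, float]
    u1_prob: float = 0.8
    cluster_weights: np.ndarray | None = None
    mean_quality: float = 30.0
    quality_sd: float = 5.0
    error_rate: float = 0.002
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_class not in ("somatic", "gonadal"):
            raise SimulationError(f"unknown tissue_class {self.tissue_class!r}")
        mix_total = sum(self.class_mix.get(c, 0.0) for c in READ_CLASSES)
        if abs(mix_total - 1.0) > 1e-9:
            raise SimulationError(f"class_mix must sum to 1 (got {mix_total})")
        for dist in (self.pirna_length_dist, self.mirna_length_dist):
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SimulationError("length distribution must sum to 1")


@dataclass
class SyntheticGenome:
    """A generated genome: scaffolds, planted-cluster truth, known-RNA refs."""

    scaffolds: dict[str, str]
    clusters: pd.DataFrame  # cluster truth table
    known_rna: dict[str, list[tuple[str, str]]]  # class -> [(name, seq)]
    config: GenomeConfig = field(default=None)  # type: ignore[assignment]

    def cluster_sequence(self, cluster_id: int) -> str:
        row = self.clusters.loc[cluster_id]
        return self.scaffolds[row["scaffold"]][row["start"]: row["end"]]


_CLUSTER_COLUMNS = [
    "cluster_id", "scaffold", "start", "end", "strand_mode",
    "tandem", "n_copies", "unit_length",
    "weight_somatic", "weight_gonadal",
]


def generate_genome(config: GenomeConfig) -> SyntheticGenome:
    """Generate the synthetic genome and its truth tables.

    Deterministic for a fixed ``config.seed``. Cluster intervals are
    pairwise disjoint, separated by more than ``min_cluster_gap`` and lie
    fully within scaffold bounds; tandem clusters consist of ≥2 exact
    copies of their unit. Raises :class:`SimulationError` when the
    requested features cannot be packed into the scaffolds.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_scaffolds < 1 or config.scaffold_length < 1:
        raise SimulationError("n_scaffolds and scaffold_length must be positive")

    scaffold_names = [f"scaffold{i + 1}" for i in range(config.n_scaffolds)]
    scaffolds = {name: random_dna(rng, config.scaffold_length) for name in scaffold_names}

    rows = _plant_clusters(config, rng, scaffolds, scaffold_names)
    clusters = pd.DataFrame(rows, columns=_CLUSTER_COLUMNS).set_index(
        "cluster_id", drop=False
    )
    _assign_weights(config, rng, clusters)

    cluster_kmers = _cluster_kmer_set(scaffolds, clusters, k=26)
    known_rna = _generate_known_rna(config, rng, cluster_kmers)

    return SyntheticGenome(scaffolds=scaffolds, clusters=clusters,
                           known_rna=known_rna, config=config)


def _plant_clusters(config, rng, scaffolds, scaffold_names):
    lo, hi = config.cluster_length_range
    if config.n_clusters and (lo < 32 or hi < lo):
        raise SimulationError("cluster_length_range must satisfy 32 <= lo <= hi")
    n_tandem = int(round(config.frac_tandem * config.n_clusters))
    is_tandem = np.zeros(config.n_clusters, dtype=bool)
    if n_tandem:
        is_tandem[rng.choice(config.n_clusters, size=n_tandem, replace=False)] = True

    lengths = np.empty(config.n_clusters, dtype=int)
    copies = np.zeros(config.n_clusters, dtype=int)
    c_lo, c_hi = config.tandem_copy_range
    if n_tandem and c_lo < 2:
        raise SimulationError("tandem_copy_range must be >= 2 copies")
    for i in range(config.n_clusters):
        if is_tandem[i]:
            copies[i] = rng.integers(c_lo, c_hi + 1)
            lengths[i] = copies[i] * config.tandem_unit_length
        else:
            lengths[i] = rng.integers(lo, hi + 1)

    # round-robin assignment to scaffolds, then random placement with gaps
    per_scaffold: dict[str, list[int]] = {name: [] for name in scaffold_names}
    order = rng.permutation(config.n_clusters)
    for j, cid in enumerate(order):
        per_scaffold[scaffold_names[j % config.n_scaffolds]].append(int(cid))

    gap = config.min_cluster_gap
    rows = []
    for name in scaffold_names:
        cids = per_scaffold[name]
        if not cids:
            continue
        need = int(lengths[cids].sum()) + gap * (len(cids) + 1)
        if need > config.scaffold_length:
            raise SimulationError(
                f"infeasible packing: {len(cids)} clusters totalling "
                f"{int(lengths[cids].sum())} bp plus {gap} bp gaps need {need} bp "
                f"but {name} is {config.scaffold_length} bp"
            )
        slack = config.scaffold_length - need
        extra = rng.multinomial(slack, np.full(len(cids) + 1, 1.0 / (len(cids) + 1)))
        pos = gap + extra[0]
        seq = scaffolds[name]
        for k, cid in enumerate(cids):
            start, end = pos, pos + int(lengths[cid])
            if is_tandem[cid]:
                unit = random_dna(rng, config.tandem_unit_length)
                seq = seq[:start] + unit * int(copies[cid]) + seq[end:]
            mode = ("bidirectional" if rng.random() < config.frac_bidirectional
                    else ("unidirectional+" if rng.random() < 0.5 else "unidirectional-"))
            rows.append({
                "cluster_id": cid, "scaffold": name, "start": start, "end": end,
                "strand_mode": mode, "tandem": bool(is_tandem[cid]),
                "n_copies": int(copies[cid]),
                "unit_length": config.tandem_unit_length if is_tandem[cid] else 0,
                "weight_somatic": 0.0, "weight_gonadal": 0.0,
            })
            pos = end + gap + extra[k + 1]
        scaffolds[name] = seq
    rows.sort(key=lambda r: r["cluster_id"])
    return rows


def _assign_weights(config, rng, clusters: pd.DataFrame) -> None:
    n = len(clusters)
    if n == 0:
        return
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    gonad_only = np.zeros(n, dtype=bool)
    n_gonad = int(round(config.frac_gonad_specific * n))
    if n_gonad:
        gonad_only[rng.choice(n, size=n_gonad, replace=False)] = True
    w_som = np.where(gonad_only, 0.0, base)
    w_gon = base * rng.lognormal(0.0, 0.25, size=n)  # mild tissue modulation
    clusters["weight_somatic"] = w_som
    clusters["weight_gonadal"] = w_gon


def _cluster_kmer_set(scaffolds, clusters, k: int) -> set[str]:
    kmers: set[str] = set()
    for _, row in clusters.iterrows():
        seq = scaffolds[row["scaffold"]][row["start"]: row["end"]]
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                kmers.add(strand_seq[i: i + k])
    return kmers


def _generate_known_rna(config, rng, forbidden_kmers: set[str]):
    """Known-RNA reference sets sharing no 26-mer with planted clusters."""
    counts = {c: max(1, int(round(_KNOWN_SPLIT[c] * config.n_known_rna_loci)))
              for c in KNOWN_RNA_CLASSES}
    if config.n_known_rna_loci == 0:
        return {c: [] for c in KNOWN_RNA_CLASSES}
    refs: dict[str, list[tuple[str, str]]] = {}
    for cls in KNOWN_RNA_CLASSES:
        length = _KNOWN_LENGTHS[cls]
        seqs = []
        for i in range(counts[cls]):
            for _ in range(100):
                seq = random_dna(rng, length)
                if not _shares_kmer(seq, forbidden_kmers, 26):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise SimulationError("could not draw a known-RNA reference "
                                      "disjoint from planted clusters")
            seqs.append((f"{cls}_{i + 1}", seq))
        refs[cls] = seqs
    return refs


def _shares_kmer(seq: str, kmers: set[str], k: int) -> bool:
    return any(seq[i: i + k] in kmers for i in range(len(seq) - k + 1))


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "read_id", "library", "true_class", "scaffold", "start", "end", "strand",
    "cluster_id", "source", "length", "n_errors", "five_prime_t",
]


def simulate_library(
    genome: SyntheticGenome, profile: LibraryProfile
) -> tuple[list[SmallRNARead], pd.DataFrame]:
    """Simulate one FASTQ library from the planted genome.

    Returns the reads (adapter appended, Phred+33 qualities) and a truth
    table with one row per read. Deterministic for a fixed
    ``profile.seed``. piRNA-like reads are exact genomic substrings of
    planted cluster intervals on the planted strand(s) before error
    injection; the 5′ base is a T with probability ``u1_prob`` exactly,
    achieved by sampling start sites conditional on the genomic base.
    """
    rng = np.random.default_rng(profile.seed)
    if profile.n_reads == 0:
        return [], pd.DataFrame(columns=_TRUTH_COLUMNS)

    mix = np.array([profile.class_mix.get(c, 0.0) for c in READ_CLASSES])
    n_per_class = rng.multinomial(profile.n_reads, mix)

    blocks = []  # list of dicts of column arrays/lists
    maker = {"pirna_like": _make_pirna_reads, "mirna_like": _make_mirna_reads,
             "known_rna": _make_known_reads, "noise": _make_noise_reads}
    for cls, n in zip(READ_CLASSES, n_per_class):
        if n > 0:
            blocks.append(maker[cls](genome, profile, rng, int(n)))

    seqs: list[str] = []
    truth_rows: dict[str, list] = {c: [] for c in _TRUTH_COLUMNS[2:9]}
    for b in blocks:
        seqs.extend(b["seq"])
        for c in truth_rows:
            truth_rows[c].extend(b[c])

    n_total = len(seqs)
    perm = rng.permutation(n_total)
    seqs = [seqs[i] for i in perm]
    truth = pd.DataFrame({c: np.asarray(v, dtype=object)[perm]
                          for c, v in truth_rows.items()})

    seqs, n_errors = _inject_errors(seqs, profile.error_rate, rng)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n_total)
    five_prime_t = np.fromiter((s[:1] == "T" for s in seqs), dtype=bool, count=n_total)

    ids = [f"{profile.name}_r{i + 1:07d}" for i in range(n_total)]
    quals = _make_qualities(rng, lengths + len(profile.adapter),
                            profile.mean_quality, profile.quality_sd)
    reads = [
        SmallRNARead(id=ids[i], sequence=seqs[i] + profile.adapter,
                     qualities=quals[i], library=profile.name)
        for i in range(n_total)
    ]

    truth.insert(0, "library", profile.name)
    truth.insert(0, "read_id", ids)
    truth["length"] = lengths
    truth["n_errors"] = n_errors
    truth["five_prime_t"] = five_prime_t
    for col in ("start", "end", "cluster_id"):
        truth[col] = pd.to_numeric(truth[col], errors="coerce").astype("Int64")

    _check_u1(truth, profile)
    return reads, truth


def _check_u1(truth: pd.DataFrame, profile: LibraryProfile) -> None:
    pir = truth[truth["true_class"] == "pirna_like"]
    if len(pir) < 100:
        return
    achieved = float(pir["five_prime_t"].mean())
    # allow for sequencing-error flips plus sampling noise before warning
    sd = np.sqrt(profile.u1_prob * (1 - profile.u1_prob) / len(pir))
    if abs(achieved - profile.u1_prob) > 4 * sd + 2 * profile.error_rate:
        warnings.warn(
            f"{profile.name}: achieved 5'U rate {achieved:.3f} differs from "
            f"requested {profile.u1_prob:.3f} (cluster base composition limit)",
            stacklevel=3,
        )


def _make_pirna_reads(genome, profile, rng, n):
    clusters = genome.clusters
    if len(clusters) == 0:
        raise SimulationError("pirna_like reads requested but no planted clusters")
    if profile.cluster_weights is not None:
        w = np.asarray(profile.cluster_weights, dtype=float)
        if len(w) != len(clusters):
            raise SimulationError("cluster_weights length != number of clusters")
    else:
        col = "weight_somatic" if profile.tissue_class == "somatic" else "weight_gonadal"
        w = clusters[col].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise SimulationError("all cluster weights are zero for this profile")
    w = w / w.sum()

    cids = clusters["cluster_id"].to_numpy()
    cidx = rng.choice(len(clusters), size=n, p=w)
    lens_avail = np.array(sorted(profile.pirna_length_dist))
    lens = lens_avail[rng.choice(len(lens_avail), size=n,
                                 p=[profile.pirna_length_dist[k] for k in lens_avail])]
    want_t = rng.random(n) < profile.u1_prob

    modes = clusters["strand_mode"].to_numpy()
    strands = np.empty(n, dtype="U1")
    uni = np.array([m != "bidirectional" for m in modes])[cidx]
    strands[uni] = np.array([m[-1] if m != "bidirectional" else "+" for m in modes])[cidx][uni]
    strands[~uni] = np.where(rng.random((~uni).sum()) < 0.5, "+", "-")

    starts_rel = np.empty(n, dtype=np.int64)
    cl_seq = {int(c): genome.cluster_sequence(int(c)) for c in np.unique(cids[cidx])}
    cl_arr = {c: encode(s) for c, s in cl_seq.items()}

    # group reads by (cluster, strand, length, wanted 5' base) and sample
    # start offsets vectorised within each group
    key = (cidx.astype(np.int64) * 1000 + lens) * 4 \
        + np.where(strands == "+", 0, 2) + want_t
    order = np.argsort(key, kind="stable")
    bounds = np.flatnonzero(np.r_[True, np.diff(key[order]) != 0, True])
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        sel = order[b0:b1]
        c = int(cids[cidx[sel[0]]])
        L = int(lens[sel[0]])
        s = strands[sel[0]]
        want = bool(want_t[sel[0]])
        arr = cl_arr[c]
        n_off = len(arr) - L + 1
        if n_off <= 0:
            raise SimulationError(f"cluster {c} shorter than read length {L}")
        if s == "+":
            is_t = arr[:n_off] == ord("T")
        else:  # 5' base of a minus-strand read is the complement of the 3' genomic base
            is_t = arr[L - 1:] == ord("A")
        valid = np.flatnonzero(is_t if want else ~is_t)
        if len(valid) == 0:
            valid = np.arange(n_off)  # composition limit; truth records reality
        starts_rel[sel] = valid[rng.integers(0, len(valid), size=len(sel))]

    cl_start = clusters["start"].to_numpy()[cidx]
    scaffs = clusters["scaffold"].to_numpy()[cidx]
    starts = cl_start + starts_rel
    seqs = []
    for i in range(n):
        c = int(cids[cidx[i]])
        sub = cl_seq[c][starts_rel[i]: starts_rel[i] + lens[i]]
        seqs.append(sub if strands[i] == "+" else revcomp(sub))
    return {
        "seq": seqs, "true_class": ["pirna_like"] * n,
        "scaffold": list(scaffs), "start": list(starts),
        "end": list(starts + lens), "strand": list(strands),
        "cluster_id": list(cids[cidx]), "source": list(scaffs),
    }


def _pick_refs(refs, rng, n):
    idx = rng.integers(0, len(refs), size=n)
    return [refs[i] for i in idx]


def _make_mirna_reads(genome, profile, rng, n):
    refs = genome.known_rna.get("miRNA", [])
    if not refs:
        raise SimulationError("mirna_like reads requested but no miRNA references")
    lens_avail = np.array(sorted(profile.mirna_length_dist))
    lens = lens_avail[rng.choice(len(lens_avail), size=n,
                                 p=[profile.mirna_length_dist[k] for k in lens_avail])]
    chosen = _pick_refs(refs, rng, n)
    seqs, sources = [], []
    for (name, ref), L in zip(chosen, lens):
        seqs.append(ref[: min(int(L), len(ref))])  # 5'-anchored mature fragment
        sources.append(name)
    return _nongenomic_block(seqs, "mirna_like", sources)


def _make_known_reads(genome, profile, rng, n):
    pool = [item for cls in ("rRNA", "tRNA", "snRNA", "snoRNA")
            for item in genome.known_rna.get(cls, [])]
    if not pool:
        raise SimulationError("known_rna reads requested but no references")
    chosen = _pick_refs(pool, rng, n)
    lens = rng.integers(16, 35, size=n)
    seqs, sources = [], []
    for (name, ref), L in zip(chosen, lens):
        L = min(int(L), len(ref))
        start = int(rng.integers(0, len(ref) - L + 1))
        frag = ref[start: start + L]
        if rng.random() < 0.5:  # degradation fragments land on either strand
            frag = revcomp(frag)
        seqs.append(frag)
        sources.append(name)
    return _nongenomic_block(seqs, "known_rna", sources)


def _make_noise_reads(genome, profile, rng, n):
    lens = rng.integers(15, 36, size=n)
    base = encode("ACGT")
    seqs = [decode(base[rng.integers(0, 4, size=int(L))]) for L in lens]
    return _nongenomic_block(seqs, "noise", ["random"] * n)


def _nongenomic_block(seqs, cls, sources):
    n = len(seqs)
    return {
        "seq": seqs, "true_class": [cls] * n, "scaffold": [""] * n,
        "start": [None] * n, "end": [None] * n, "strand": ["."] * n,
        "cluster_id": [None] * n, "source": sources,
    }


def _inject_errors(seqs, error_rate, rng):
    n = len(seqs)
    n_errors = np.zeros(n, dtype=np.int64)
    if error_rate <= 0:
        return seqs, n_errors
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    counts = rng.binomial(lengths, error_rate)
    hit = np.flatnonzero(counts)
    bases = "ACGT"
    for i in hit:
        s = list(seqs[i])
        pos = rng.choice(len(s), size=min(int(counts[i]), len(s)), replace=False)
        for p in pos:
            alts = [b for b in bases if b != s[p]]
            s[p] = alts[int(rng.integers(0, 3))]
        seqs[i] = "".join(s)
        n_errors[i] = len(pos)
    return seqs, n_errors


def _make_qualities(rng, lengths, mean_q, sd_q):
    """Per-read mean Phred drawn once, small per-base jitter around it."""
    n = len(lengths)
    read_mean = rng.normal(mean_q, sd_q, size=n)
    total = int(lengths.sum())
    flat = np.repeat(read_mean, lengths) + rng.normal(0.0, 2.0, size=total)
    flat = np.clip(np.rint(flat), 2, 41).astype(np.uint8)
    out = []
    offs = np.r_[0, np.cumsum(lengths)]
    for i in range(n):
        out.append(phred_to_string(flat[offs[i]: offs[i + 1]]))
    return out


# ---------------------------------------------------------------------------
# study-level defaults
# ---------------------------------------------------------------------------

_SOMATIC_MIX = {"pirna_like": 0.45, "mirna_like": 0.25, "known_rna": 0.20, "noise": 0.10}
_GONADAL_MIX = {"pirna_like": 0.75, "mirna_like": 0.00, "known_rna": 0.15, "noise": 0.10}
_PIRNA_LEN = {26: 0.04, 27: 0.06, 28: 0.10, 29: 0.25, 30: 0.30, 31: 0.25}
_MIRNA_LEN = {20: 0.08, 21: 0.22, 22: 0.30, 23: 0.25, 24: 0.15}

TISSUES = ("Ma", "Ad", "Gi", "Go")  # mantle, adductor, gill, gonad


def default_study_profiles(
    n_reads: int = 200_000, u1_prob: float = 0.8, seed: int = 0
) -> list[LibraryProfile]:
    """Eight-library study design: 2 replicates × {Ma, Ad, Gi, Go}."""
    ss = np.random.SeedSequence(seed).generate_state(8) % (2 ** 31)
    profiles = []
    i = 0
    for rep in (1, 2):
        for tis in TISSUES:
            gonadal = tis == "Go"
            profiles.append(LibraryProfile(
                name=f"{tis}{rep}",
                tissue_class="gonadal" if gonadal else "somatic",
                n_reads=n_reads,
                class_mix=dict(_GONADAL_MIX if gonadal else _SOMATIC_MIX),
                pirna_length_dist=dict(_PIRNA_LEN),
                mirna_length_dist=dict(_MIRNA_LEN),
                u1_prob=u1_prob,
                seed=int(ss[i]),
            ))
            i += 1
    return profiles


def simulate_study(
    genome: SyntheticGenome, profiles: list[LibraryProfile]
) -> tuple[dict[str, list[SmallRNARead]], pd.DataFrame]:
    """Simulate every library of a study; returns reads per library and the
    concatenated read-truth table."""
    reads_by_lib: dict[str, list[SmallRNARead]] = {}
    truths = []
    for profile in profiles:
        reads, truth = simulate_library(genome, profile)
        reads_by_lib[profile.name] = reads
        truths.append(truth)
    truth = (pd.concat(truths, ignore_index=True)
             if truths else pd.DataFrame(columns=_TRUTH_COLUMNS))
    return reads_by_lib, truth


def expected_five_prime_t(u1_prob: float, error_rate: float) -> float:
    """Expected observed 5′T read fraction under the generator's forward
    model: the planted rate attenuated by the substitution-error channel
    (an error always changes the base, to each alternative equally)."""
    return u1_prob * (1 - error_rate) + (1 - u1_prob) * error_rate / 3


def rescale_profile(profile: LibraryProfile, n_reads: int) -> LibraryProfile:
    """Copy of a profile with a different library size (same seed)."""
    return replace(profile, n_reads=n_reads)
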