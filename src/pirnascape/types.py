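"""Core record types flowing through the pipeline.

Coordinates are 0-based half-open throughout (BED convention); strand is
``+``/``-``. Reads carry Phred scores as a quality string aligned to the
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(slots=True)
class SmallRNARead:
    """A single sequenced small RNA read.

    ``qualities`` is the Phred+33 string, same length as ``sequence``.
    """

    id: str
    sequence: str
    qualities: str
    library: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True, frozen=True)
class MappingRecord:
    """One placement of a read on the genome (substitution-only alignment)."""

    read_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(slots=True)
class UniqueSequenceRecord:
    """A collapsed unique putative piRNA sequence.

    ``counts``/``rpm`` map library label to read count / reads-per-million.
    ``loci`` is the all-hits placement list shared by every constituent read.
    ``locus_class`` is one of ``unique-locus``, ``multi-locus``,
    ``multi-tandem`` (the latter meaning ≥2 placements on one scaffold).
    """

    sequence: str
    counts: dict[str, int]
    loci: list[MappingRecord]
    rpm: dict[str, float] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_scaffolds(self) -> int:
        return len({m.scaffold for m in self.loci})

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def locus_class(self) -> str:
        if self.n_loci == 1:
            return "unique-locus"
        if self.n_loci > self.n_scaffolds:  # pigeonhole: some scaffold holds ≥2
            return "multi-tandem"
        return "multi-locus"


@dataclass(slots=True)
class Cluster:
    """A called piRNA cluster: merged mapping loci passing the coverage floor."""

    name: str
    scaffold: str
    start: int
    end: int
    counts: dict[str, int] = field(default_factory=dict)
    rpkm: dict[str, float] = field(default_factory=dict)
    plus_fraction: float = float("nan")
    directionality: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


class StepCounts:
    """Per-library read counts at each processing step (raw, step1..step4).

    Counts are non-increasing across steps for every library; ``removed``
    tracks per-step attrition with a reason label so every input read is
    accounted for exactly once.
    """

    STEPS = ("raw", "step1", "step2", "step3", "step4")

    def __init__(self) -> None:
        self.counts: dict[str, dict[str, int]] = {}
        self.removed: dict[str, dict[str, int]] = {}

    def record(self, library: str, step: str, count: int) -> None:
        if step not in self.STEPS:
            raise ValueError(f"unknown step {step!r}")
        row = self.counts.setdefault(library, {})
        prev = [row[s] for s in self.STEPS if s in row]
        if prev and count > prev[-1]:
            raise ValueError(
                f"{library}: count at {step} ({count}) exceeds previous ({prev[-1]})"
            )
        row[step] = count

    def record_removed(self, library: str, reason: str, count: int) -> None:
        row = self.removed.setdefault(library, {})
        row[reason] = row.get(reason, 0) + count

    def get(self, library: str, step: str) -> int:
        return self.counts[library][step]

    def as_table(self):
        """Counts as a pandas DataFrame, libraries × steps."""
        import pandas as pd

        return pd.DataFrame(self.counts).T.reindex(columns=list(self.STEPS))

    def accounted(self, library: str) -> bool:
        """True if raw == survivors + all removals for the library."""
        row = self.counts.get(library, {})
        if "raw" not in row:
            return False
        last = [row[s] for s in self.STEPS if s in row][-1]
        removed = sum(self.removed.get(library, {}).values())
        return row["raw"] == last + removed
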