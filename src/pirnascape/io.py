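"""File I/O: FASTQ/FASTA via Biopython, BED/bedGraph/TSV writers.

All genomic coordinates written to BED-family files are 0-based
half-open; human-readable TSV reports keep the same convention and say so
in their headers.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import SmallRNARead


def read_fastq(path: str, library: str | None = None) -> Iterator[SmallRNARead]:
    """Stream reads from a Phred+33 FASTQ file."""
    lib = library if library is not None else os.path.basename(path).split(".")[0]
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield SmallRNARead(id=title.split()[0], sequence=seq.upper(),
                               qualities=qual, library=lib)


def write_fastq(path: str, reads: Iterable[SmallRNARead]) -> int:
    n = 0
    with open(path, "w") as handle:
        for r in reads:
            handle.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")
            n += 1
    return n


def read_fasta(path: str) -> dict[str, str]:
    """FASTA file as an ordered name -> sequence dict (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i: i + width] + "\n")


def write_bed6(path: str, rows: Iterable[tuple[str, int, int, str, int | float, str]]) -> None:
    """BED6 writer: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as handle:
        for chrom, start, end, name, score, strand in rows:
            handle.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_bedgraph(path: str, rows: Iterable[tuple[str, int, int, float]],
                   track_name: str = "coverage") -> None:
    with open(path, "w") as handle:
        handle.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in rows:
            handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
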