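"""File format helpers (FASTA, FASTQ, GFF3, BED, tables).

Reading of FASTA goes through Biopython; FASTQ is read with a minimal
4-line iterator because the pipeline streams millions of short reads and
only ever needs (id, sequence, quality).  Writers are deliberately plain so
that identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "read_fasta",
    "write_fasta",
    "iter_fastq",
    "write_fastq",
    "write_gff3",
    "read_gff3_genes",
    "write_bed",
    "read_bed",
]

_FASTA_WIDTH = 70


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = _FASTA_WIDTH) -> None:
    """Write sequences wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, quality) from a 4-line FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header!r} in {path}")
            yield header[1:].split()[0], seq, qual


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in reads)


def write_gff3(features: list[tuple], path: str | Path) -> None:
    """Write GFF3 rows given 0-based half-open feature tuples.

    Each feature is (chrom, source, type, start0, end0, strand, attributes);
    coordinates are rendered 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, source, ftype, start, end, strand, attrs in features:
            fh.write(f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")


def read_gff3_genes(path: str | Path) -> list[tuple]:
    """Extract gene-level spans as (chrom, start0, end0, strand, gene_id)."""
    genes: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"GFF3 parse error at line {lineno}: "
                                 f"expected 9 columns, got {len(parts)}")
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError as exc:
                raise ValueError(f"GFF3 parse error at line {lineno}: {exc}") from exc
            gid = parts[8].split("ID=")[-1].split(";")[0]
            genes.append((parts[0], start, end, parts[6], gid))
    return genes


def write_bed(intervals: list[tuple], path: str | Path) -> None:
    """Write (chrom, start0, end0[, name]) intervals as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv[3] if len(iv) > 3 else "."
            fh.write(f"{iv[0]}\t{iv[1]}\t{iv[2]}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple]:
    out: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED parse error at line {lineno}")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
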