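"""Readers and writers for the on-disk formats shared by the pipeline.

FASTA goes through Biopython; BED conversion between the on-disk 0-based
half-open convention and the package's 1-based inclusive intervals happens
here and nowhere else.  All text formats are UTF-8 and transparently
gzipped when the path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Genome, GenomicInterval, UNSTRANDED

PathLike = Union[str, Path]

ENHANCER_SOURCES = {"GeneHancer", "SEdb2.0", "Ensembl", "ENCODE"}


def _open_text(path: PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> Genome:
    """Load a FASTA file into a :class:`Genome` (sequences uppercased)."""
    with _open_text(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return Genome(seqs)


def write_fasta(genome: Genome, path: PathLike, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(name)), id=name, description="")
        for name in genome
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_reads(path: PathLike) -> List[Tuple[str, str]]:
    """Read sequencing reads from FASTA or FASTQ as ``(read_id, sequence)``."""
    fmt = "fastq" if str(path).rstrip(".gz").endswith(("fq", "fastq")) else "fasta"
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def write_fastq(reads: Iterable[Tuple[str, str]], path: PathLike) -> None:
    """Write ``(read_id, sequence)`` pairs as FASTQ with uniform quality."""
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 else UNSTRANDED
            out.append(GenomicInterval(chrom, start0 + 1, end0, strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: PathLike,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write intervals as BED6 (coordinates converted to 0-based half-open)."""
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score:g}\t"
                f"{iv.strand if iv.strand != UNSTRANDED else '.'}\n"
            )


# ---------------------------------------------------------------------------
# Enhancer annotation TSV (curated table dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnhancerAnnotation:
    """One curated enhancer annotation row.

    ``genes`` is the (possibly empty) list of genes the source database
    lists as regulated by the enhancer.
    """

    enhancer_id: str
    source: str
    interval: GenomicInterval
    genes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source not in ENHANCER_SOURCES:
            raise ValueError(
                f"unknown enhancer source {self.source!r}; "
                f"expected one of {sorted(ENHANCER_SOURCES)}"
            )


def read_enhancer_table(path: PathLike) -> List[EnhancerAnnotation]:
    """Read a curated enhancer annotation TSV.

    Columns (tab-separated, header required): ``enhancer_id``, ``source``,
    ``chrom``, ``start``, ``stop``, ``genes`` with genes semicolon-separated
    (empty field = no indicated regulation).  Coordinates are 1-based
    inclusive as printed in the source databases.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"enhancer_id", "source", "chrom", "start", "stop", "genes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enhancer table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        genes = tuple(g.strip() for g in row.genes.split(";") if g.strip())
        out.append(
            EnhancerAnnotation(
                enhancer_id=row.enhancer_id,
                source=row.source,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.stop)),
                genes=genes,
            )
        )
    return out


def write_enhancer_table(
    annotations: Sequence[EnhancerAnnotation], path: PathLike
) -> None:
    rows = [
        {
            "enhancer_id": a.enhancer_id,
            "source": a.source,
            "chrom": a.interval.chrom,
            "start": a.interval.start,
            "stop": a.interval.end,
            "genes": ";".join(a.genes),
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSS / gene definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    tss: int
    strand: str


def read_tss_table(path: PathLike) -> List[TssRecord]:
    """Read gene TSS definitions.

    Accepts either a 4-column TSV (``gene``, ``chrom``, ``tss``, ``strand``,
    header required) or GFF3 (detected by suffix), where each ``gene`` /
    ``mRNA`` feature contributes one TSS (start for '+', end for '-';
    identifier from ``ID``/``gene_id``/``Name`` attributes).
    """
    name = str(path)
    if name.rstrip(".gz").endswith(("gff", "gff3")):
        return _read_tss_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return [
        TssRecord(r.gene, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def _read_tss_gff3(path: PathLike) -> List[TssRecord]:
    out: List[TssRecord] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in {"gene", "mRNA", "transcript"}:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene = attrs.get("gene_id") or attrs.get("Name") or attrs.get("ID")
            if gene is None:
                continue
            strand = f[6]
            tss = int(f[3]) if strand != "-" else int(f[4])
            out.append(TssRecord(gene, f[0], tss, strand))
    return out


def write_tss_table(records: Sequence[TssRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"gene": r.gene, "chrom": r.chrom, "tss": r.tss, "strand": r.strand}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
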