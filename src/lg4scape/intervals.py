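"""Coordinate conventions and interval algebra.

All externally visible coordinates in this package are 1-based and
inclusive on both ends, matching the ``Chr5:551935:556936`` locus notation
used by Ensembl and by the enhancer annotation tables this package
consumes.  Conversion to BED's 0-based half-open convention happens only
at the I/O boundary (:mod:`lg4scape.io`).

Upstream promoter windows are specified by a pair of offsets
``(offset_far, offset_near)`` measured in bp upstream of a TSS and denote
the half-open span ``[-offset_far, -offset_near)``; its length is therefore
``offset_far - offset_near``.  This is the only convention consistent with
all three deletion-construct lengths handled here (982, 148 and 35 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

_VALID_STRANDS = {PLUS, MINUS, UNSTRANDED}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, both-ends-inclusive genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        First and last base of the interval, 1-based inclusive,
        ``1 <= start <= end``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base.

        Strand-agnostic; intervals on different chromosomes never overlap.
        """
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # Chr5:551935:556936 style
        return f"{self.chrom}:{self.start}:{self.end}"


def length_of(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (``end - start + 1``)."""
    return len(interval)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Symmetric, strand-agnostic overlap predicate."""
    return a.overlaps(b)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list:
    """Merge overlapping (or within-``gap``-bp adjacent) intervals.

    Output intervals are unstranded and sorted by (chrom, start).
    """
    out: list = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if (
            out
            and out[-1].chrom == iv.chrom
            and iv.start <= out[-1].end + 1 + gap
        ):
            prev = out[-1]
            out[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end)
            )
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


class Genome:
    """In-memory genome: mapping of chromosome name to uppercase DNA.

    Sequences are stored uppercase over {A, C, G, T, N}.  Minus-strand
    fetches return the reverse complement of the plus-strand slice.
    """

    def __init__(self, sequences: Dict[str, str]):
        self._seqs: Dict[str, str] = {
            name: seq.upper() for name, seq in sequences.items()
        }

    @property
    def chromosomes(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        """Full plus-strand sequence of a chromosome."""
        return self._seqs[chrom]

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; '-' strand returns the reverse complement."""
        seq = self._seqs[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"{interval} extends past end of {interval.chrom} "
                f"(length {len(seq)})"
            )
        sub = seq[interval.start - 1 : interval.end]
        if interval.strand == MINUS:
            return reverse_complement(sub)
        return sub


@dataclass(frozen=True)
class UpstreamWindow:
    """An upstream promoter window ``[-offset_far, -offset_near)`` of a TSS."""

    gene: str
    tss: int
    strand: str
    offset_far: int
    offset_near: int = 0

    def __post_init__(self) -> None:
        if self.offset_near < 0:
            raise ValueError("offset_near must be >= 0")
        if self.offset_far <= self.offset_near:
            raise ValueError(
                f"offset_far ({self.offset_far}) must exceed offset_near "
                f"({self.offset_near})"
            )

    def __len__(self) -> int:
        return self.offset_far - self.offset_near


def upstream_window_length(offset_far: int, offset_near: int) -> int:
    """Length in bp of the half-open upstream span ``[-far, -near)``.

    Rejects ``offset_far <= offset_near``.
    """
    if offset_far <= offset_near:
        raise ValueError(
            f"offset_far ({offset_far}) must exceed offset_near ({offset_near})"
        )
    if offset_near < 0:
        raise ValueError("offset_near must be >= 0")
    return offset_far - offset_near


def resolve_window(
    chrom: str,
    tss: int,
    strand: str,
    window: UpstreamWindow,
    genome: Optional[Genome] = None,
    strand_resolved: bool = True,
) -> Tuple[GenomicInterval, bool]:
    """Place an upstream window on genome coordinates.

    For a '+' strand gene the window lies at
    ``[tss - offset_far, tss - offset_near - 1]``; for a '-' strand gene it
    is mirrored downstream of the TSS in genome coordinates,
    ``[tss + offset_near + 1, tss + offset_far]``.  With
    ``strand_resolved=False`` every gene is treated as '+' (windows always
    taken to the left of the TSS in genome coordinates).

    Returns ``(interval, truncated)`` where ``truncated`` flags a window
    clipped at a chromosome edge.
    """
    far, near = window.offset_far, window.offset_near
    eff_strand = strand if strand_resolved else PLUS
    if eff_strand == MINUS:
        start, end = tss + near + 1, tss + far
    else:
        start, end = tss - far, tss - near - 1

    truncated = False
    if start < 1:
        start, truncated = 1, True
    if genome is not None:
        clen = genome.chrom_length(chrom)
        if end > clen:
            end, truncated = clen, True
    if end < start:
        raise ValueError(
            f"upstream window of {window.gene} does not intersect {chrom}"
        )
    return GenomicInterval(chrom, start, end, strand), truncated
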