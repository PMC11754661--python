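"""G-run detection, minimal G4 motif finding, and LG4 locus calling.

The minimal G4-capable motif is four runs of >= 3 guanines separated by
short loops (``GGGnGGGnGGGnGGG``).  A long G4-rich locus (LG4) is a
kilobase-scale region whose density of GGG repeats reaches a threshold
(default 80 repeats per 1000 bp on either strand).  "GGG repeats" are
counted by non-overlapping tiling of each maximal G-run into GGG units
(``floor(run_length / 3)``); counting whole runs instead is available via
``counting_mode="runs"``.

Minus-strand G content is read as C runs on the plus-strand text, so all
reported coordinates stay in plus-strand space.  N bases never match G or
C; a run interrupted by N is two runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .intervals import (
    Genome,
    GenomicInterval,
    MINUS,
    PLUS,
    merge_intervals,
)

TILING = "tiling"
RUNS = "runs"


@dataclass(frozen=True)
class GRun:
    """A maximal run of >= min_run consecutive G on one strand.

    ``start``/``end`` are 1-based inclusive positions on the plus-strand
    text of the scanned sequence (for '-' strand runs these are the
    positions of the complementary C run).
    """

    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class G4Motif:
    """A minimal G4 motif: four G-runs with loops in [loop_min, loop_max]."""

    start: int
    end: int
    strand: str
    runs: Tuple[GRun, GRun, GRun, GRun]
    loop_lengths: Tuple[int, int, int]


@dataclass(frozen=True)
class LG4Call:
    """A called long G4-rich locus."""

    interval: GenomicInterval
    ggg_count_plus: int
    ggg_count_minus: int
    peak_density: float  # repeats per 1000 bp, best scan window
    qualifying_strand: str  # '+', '-' or 'both'

    @property
    def ggg_count_total(self) -> int:
        return self.ggg_count_plus + self.ggg_count_minus


def find_g_runs(seq: str, min_run: int = 3, strand: str = PLUS) -> List[GRun]:
    """All maximal runs of >= ``min_run`` consecutive G (or C for '-').

    Runs are sorted by start and non-overlapping by maximality.  The empty
    sequence yields an empty list.
    """
    base = "G" if strand == PLUS else "C"
    out: List[GRun] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_run:
                out.append(GRun(i + 1, j, strand))
            i = j
        else:
            i += 1
    return out


def count_ggg_repeats(
    seq: str,
    strand: str = PLUS,
    min_run: int = 3,
    counting_mode: str = TILING,
) -> int:
    """Number of GGG repeats on one strand of ``seq``.

    ``counting_mode="tiling"`` (default) tiles each maximal G-run into
    non-overlapping GGG units, contributing ``floor(run_length / 3)``;
    ``"runs"`` counts each maximal run of >= ``min_run`` G once.
    """
    runs = find_g_runs(seq, min_run=min_run, strand=strand)
    if counting_mode == TILING:
        return sum(r.length // 3 for r in runs)
    if counting_mode == RUNS:
        return len(runs)
    raise ValueError(f"unknown counting_mode {counting_mode!r}")


def find_min_g4_motifs(
    seq: str,
    loop_min: int = 1,
    loop_max: int = 7,
    min_run: int = 3,
    strand: str = PLUS,
) -> List[G4Motif]:
    """Non-overlapping minimal G4 motifs, resolved leftmost-first.

    A motif is four consecutive maximal G-runs (>= ``min_run``) whose three
    inter-run gaps (loops) all lie in ``[loop_min, loop_max]``.  Scanning is
    greedy left to right: the leftmost run that anchors a valid motif emits
    it, and scanning resumes after the motif's last base.
    """
    if loop_min < 1:
        raise ValueError("loop_min must be >= 1")
    runs = find_g_runs(seq, min_run=min_run, strand=strand)
    out: List[G4Motif] = []
    i = 0
    while i + 3 < len(runs):
        quad = runs[i : i + 4]
        loops = tuple(
            quad[k + 1].start - quad[k].end - 1 for k in range(3)
        )
        if all(loop_min <= lp <= loop_max for lp in loops):
            out.append(
                G4Motif(
                    start=quad[0].start,
                    end=quad[3].end,
                    strand=strand,
                    runs=tuple(quad),
                    loop_lengths=loops,
                )
            )
            i += 4  # resume after the motif: non-overlapping report
        else:
            i += 1
    return out


def _window_starts(chrom_len: int, window: int, step: int) -> List[int]:
    """Sliding starts 1, 1+step, ... plus one final partial window."""
    if chrom_len <= window:
        return [1]
    starts = list(range(1, chrom_len - window + 2, step))
    if starts[-1] + window - 1 < chrom_len:
        starts.append(starts[-1] + step)
    return starts


def ggg_density_profile(
    genome: Genome,
    chrom: str,
    window: int = 1000,
    step: int = 100,
    counting_mode: str = TILING,
) -> pd.DataFrame:
    """Per-window GGG repeat densities on both strands.

    Windows slide from the chromosome start; the final partial window is
    scaled by its true length.  Density is in repeats per 1000 bp.

    Returns a DataFrame with columns ``chrom, start, end, count_plus,
    count_minus, density_plus, density_minus``.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    seq = genome.sequence(chrom)
    clen = len(seq)
    rows = []
    for s in _window_starts(clen, window, step):
        e = min(s + window - 1, clen)
        sub = seq[s - 1 : e]
        wlen = e - s + 1
        cp = count_ggg_repeats(sub, PLUS, counting_mode=counting_mode)
        cm = count_ggg_repeats(sub, MINUS, counting_mode=counting_mode)
        rows.append(
            {
                "chrom": chrom,
                "start": s,
                "end": e,
                "count_plus": cp,
                "count_minus": cm,
                "density_plus": cp * 1000.0 / wlen,
                "density_minus": cm * 1000.0 / wlen,
            }
        )
    return pd.DataFrame(rows)


def _refine_span(
    seq: str,
    region_start: int,
    region_end: int,
    density_threshold: float,
    step: int,
    counting_mode: str,
) -> Tuple[int, int]:
    """Shrink a merged candidate region to its step-bin-supported span.

    Bins of ``step`` bp are tiled across the region; a bin qualifies if its
    own density (either strand) reaches the threshold.  The refined span
    runs from the first to the last qualifying bin, which anchors call
    boundaries near the dense sequence instead of the coarse window grid.
    Falls back to the full region when no single bin qualifies (diffuse
    signal near the threshold).
    """
    best_first, best_last = None, None
    for s in range(region_start, region_end + 1, step):
        e = min(s + step - 1, region_end)
        sub = seq[s - 1 : e]
        blen = e - s + 1
        dens = max(
            count_ggg_repeats(sub, PLUS, counting_mode=counting_mode),
            count_ggg_repeats(sub, MINUS, counting_mode=counting_mode),
        ) * 1000.0 / blen
        if dens >= density_threshold:
            if best_first is None:
                best_first = s
            best_last = e
    if best_first is None:
        return region_start, region_end
    return best_first, best_last


def _trim_to_runs(
    seq: str, span_start: int, span_end: int, strands: Sequence[str]
) -> Tuple[int, int]:
    """Anchor span edges to the outermost G/C run intersecting the span."""
    sub = seq[span_start - 1 : span_end]
    edges: List[Tuple[int, int]] = []
    for strand in strands:
        runs = find_g_runs(sub, strand=strand)
        if runs:
            edges.append((runs[0].start, runs[-1].end))
    if not edges:
        return span_start, span_end
    lo = min(e[0] for e in edges) + span_start - 1
    hi = max(e[1] for e in edges) + span_start - 1
    return lo, hi


def call_lg4(
    genome: Genome,
    density_threshold: float = 80.0,
    window: int = 1000,
    step: int = 100,
    min_length: int = 1000,
    counting_mode: str = TILING,
) -> List[LG4Call]:
    """Call long G4-rich loci across all chromosomes of ``genome``.

    Scan windows whose plus- or minus-strand GGG repeat density reaches
    ``density_threshold`` are merged, each merged region is refined to its
    step-bin-supported span, trimmed to the outermost contributing G/C run,
    and discarded if shorter than ``min_length``.
    """
    if density_threshold <= 0 or min_length <= 0:
        raise ValueError("thresholds must be positive")
    calls: List[LG4Call] = []
    for chrom in genome:
        seq = genome.sequence(chrom)
        prof = ggg_density_profile(
            genome, chrom, window=window, step=step, counting_mode=counting_mode
        )
        marked = prof[
            (prof.density_plus >= density_threshold)
            | (prof.density_minus >= density_threshold)
        ]
        if marked.empty:
            continue
        regions = merge_intervals(
            GenomicInterval(chrom, int(r.start), int(r.end))
            for r in marked.itertuples(index=False)
        )
        for region in regions:
            in_region = marked[
                (marked.start <= region.end) & (marked.end >= region.start)
            ]
            strands = []
            if (in_region.density_plus >= density_threshold).any():
                strands.append(PLUS)
            if (in_region.density_minus >= density_threshold).any():
                strands.append(MINUS)
            lo, hi = _refine_span(
                seq, region.start, region.end, density_threshold, step,
                counting_mode,
            )
            lo, hi = _trim_to_runs(seq, lo, hi, strands)
            if hi - lo + 1 < min_length:
                continue
            sub = seq[lo - 1 : hi]
            calls.append(
                LG4Call(
                    interval=GenomicInterval(chrom, lo, hi),
                    ggg_count_plus=count_ggg_repeats(
                        sub, PLUS, counting_mode=counting_mode
                    ),
                    ggg_count_minus=count_ggg_repeats(
                        sub, MINUS, counting_mode=counting_mode
                    ),
                    peak_density=float(
                        in_region[["density_plus", "density_minus"]].max().max()
                    ),
                    qualifying_strand="both" if len(strands) == 2 else strands[0],
                )
            )
    return calls


def composite_availability_ratio(
    lg4: LG4Call, promoters: Sequence
) -> float:
    """Ratio of an LG4's both-strand GGG repeats to the mean promoter count.

    ``promoters`` are records exposing ``triplet_count_total`` (see
    :class:`lg4scape.enrichment.PromoterRecord`).  A promoter mean of zero
    leaves the ratio undefined: NaN is returned with a warning.
    """
    if not promoters:
        raise ValueError("at least one promoter is required")
    mean_count = sum(p.triplet_count_total for p in promoters) / len(promoters)
    if mean_count == 0:
        warnings.warn(
            "mean promoter G-triplet count is zero; availability ratio "
            "undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return lg4.ggg_count_total / mean_count
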