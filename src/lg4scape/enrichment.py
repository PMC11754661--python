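"""Matched-control generation and enrichment statistics.

Covers the four statistical comparisons used around LG4 loci: enhancer
overlap enrichment against size/composition matched control loci
(unpaired one-tailed t), promoter G-triplet enrichment (Pearson
chi-square on enumerated GGG motifs), intra-neighborhood gene-fusion
counts (unpaired two-tailed t), and a Welch t kernel for reporting.

The chi-square contingency table is built on 3-bp "triplet slot" units by
default: ``[triplet_count, total_window_bp/3 - triplet_count]`` per group.
Counting each 3-bp motif once keeps groups with unequal window totals
comparable *and* keeps the statistic calibrated; building the table on raw
base-pair occupancy (3 bp per motif, available via ``table_units="bp"``)
triples every cell and with it the statistic, inflating type-I error
threefold for identical proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .g4scan import TILING, count_ggg_repeats
from .intervals import (
    Genome,
    GenomicInterval,
    MINUS,
    PLUS,
    UpstreamWindow,
    overlaps,
    resolve_window,
)
from .io import EnhancerAnnotation

CHI_SQUARE = "chi_square"
T_ONE_TAILED = "t_one_tailed"
T_TWO_TAILED = "t_two_tailed"
T_TWO_TAILED_WELCH = "t_two_tailed_welch"


@dataclass(frozen=True)
class PromoterRecord:
    """A gene promoter with its upstream-window G-triplet counts."""

    gene: str
    chrom: str
    tss: int
    strand: str
    window: GenomicInterval
    triplet_count_plus: int
    triplet_count_minus: int
    truncated: bool = False

    @property
    def triplet_count_total(self) -> int:
        return self.triplet_count_plus + self.triplet_count_minus


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one enrichment comparison."""

    statistic_name: str
    statistic: float
    df: float
    p_value: float
    effect_summary: str = ""
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Promoter triplet counting
# ---------------------------------------------------------------------------

def count_window_triplets(
    gene: str,
    chrom: str,
    tss: int,
    strand: str,
    genome: Genome,
    window_bp: int = 5000,
    counting_mode: str = TILING,
    strand_resolved: bool = True,
) -> PromoterRecord:
    """GGG repeat counts on both strands of a gene's upstream window.

    The window is the ``window_bp`` bases immediately upstream of the TSS
    (strand-resolved by default).  Windows truncated at a chromosome edge
    are flagged but still counted.
    """
    win = UpstreamWindow(gene, tss, strand, offset_far=window_bp)
    interval, truncated = resolve_window(
        chrom, tss, strand, win, genome, strand_resolved=strand_resolved
    )
    seq = genome.fetch(
        GenomicInterval(interval.chrom, interval.start, interval.end)
    )
    return PromoterRecord(
        gene=gene,
        chrom=chrom,
        tss=tss,
        strand=strand,
        window=interval,
        triplet_count_plus=count_ggg_repeats(
            seq, PLUS, counting_mode=counting_mode
        ),
        triplet_count_minus=count_ggg_repeats(
            seq, MINUS, counting_mode=counting_mode
        ),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Matched controls
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def matched_control_loci(
    loci: Sequence[GenomicInterval],
    genome: Genome,
    n_sets: int,
    gc_tolerance: float = 0.02,
    seed: int = 0,
    max_tries: int = 1000,
) -> List[List[GenomicInterval]]:
    """Draw ``n_sets`` sets of length- and GC-matched control loci.

    Each control has exactly the length of its source locus, GC fraction
    within ``gc_tolerance`` of it, and overlaps neither any source locus
    nor any other control in its set.  Sampling is seeded; a locus that
    cannot be placed within ``max_tries`` draws raises a ``RuntimeError``
    naming it.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome.chrom_length(c) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    sets: List[List[GenomicInterval]] = []
    for _ in range(n_sets):
        placed: List[GenomicInterval] = []
        for locus in loci:
            want_len = len(locus)
            want_gc = _gc_fraction(genome.fetch(
                GenomicInterval(locus.chrom, locus.start, locus.end)
            ))
            ok = None
            for _try in range(max_tries):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                clen = genome.chrom_length(chrom)
                if clen < want_len:
                    continue
                start = int(rng.integers(1, clen - want_len + 2))
                cand = GenomicInterval(chrom, start, start + want_len - 1)
                if any(overlaps(cand, s) for s in loci):
                    continue
                if any(overlaps(cand, p) for p in placed):
                    continue
                if abs(_gc_fraction(genome.fetch(cand)) - want_gc) > gc_tolerance:
                    continue
                ok = cand
                break
            if ok is None:
                raise RuntimeError(
                    f"could not place a matched control for {locus} "
                    f"within {max_tries} tries"
                )
            placed.append(ok)
        sets.append(placed)
    return sets


# ---------------------------------------------------------------------------
# t-test kernels
# ---------------------------------------------------------------------------

def _t_result(
    x: np.ndarray,
    y: np.ndarray,
    tails: int,
    equal_var: bool,
    direction: str = "two-sided",
    name: str = T_TWO_TAILED,
    effect: str = "",
) -> EnrichmentResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    flags: List[str] = []
    var_x = np.var(x, ddof=1) if len(x) > 1 else 0.0
    var_y = np.var(y, ddof=1) if len(y) > 1 else 0.0
    if var_x == 0 and var_y == 0:
        flags.append("degenerate_zero_variance")
        t = 0.0
        df = float(len(x) + len(y) - 2)
        p = 0.5 if tails == 1 else 1.0
    else:
        alternative = direction if tails == 1 else "two-sided"
        res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
        t = float(res.statistic)
        df = float(res.df)
        p = float(res.pvalue)
    return EnrichmentResult(
        statistic_name=name,
        statistic=t,
        df=df,
        p_value=p,
        effect_summary=effect
        or f"mean difference = {float(np.mean(x) - np.mean(y)):.6g}",
        flags=tuple(flags),
    )


def welch_t_test(
    x: Sequence[float], y: Sequence[float], tails: int = 2
) -> EnrichmentResult:
    """Unpaired t-test with Welch's correction (Welch-Satterthwaite df).

    ``tails=1`` tests the one-sided alternative mean(x) > mean(y).
    """
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    return _t_result(
        np.asarray(x), np.asarray(y), tails=tails, equal_var=False,
        direction="greater", name=T_TWO_TAILED_WELCH if tails == 2 else T_ONE_TAILED,
    )


# ---------------------------------------------------------------------------
# Enhancer overlap enrichment
# ---------------------------------------------------------------------------

def count_annotation_overlaps(
    lg4: GenomicInterval, annotations: Sequence[EnhancerAnnotation]
) -> int:
    """Number of annotation intervals overlapping an LG4 locus.

    Any-overlap on the same chromosome counts; annotations on other
    chromosomes are ignored.
    """
    return sum(1 for a in annotations if overlaps(lg4, a.interval))


def overlap_enrichment_test(
    loci: Sequence[GenomicInterval],
    control_sets: Sequence[Sequence[GenomicInterval]],
    annotations: Sequence[EnhancerAnnotation],
    mode: str = "per_locus",
) -> EnrichmentResult:
    """One-tailed enrichment of real loci overlapping >= 1 annotation.

    ``mode="per_locus"`` (default): the per-locus overlap indicator (0/1)
    of the real loci is compared against the pooled control loci with an
    unpaired one-tailed pooled-variance t-test (alternative: real >
    control).  ``mode="per_set"`` compares the real total overlap count
    as a single observation against the per-set control totals (a
    one-sample t on the control counts, one-tailed) — this mirrors how
    such comparisons are sometimes reported, but with few control sets it
    is a weak construction and is not the default.
    """
    if len(control_sets) < 2:
        raise ValueError("need at least 2 control sets")
    real_ind = np.array(
        [
            1.0 if count_annotation_overlaps(l, annotations) > 0 else 0.0
            for l in loci
        ]
    )
    if mode == "per_locus":
        ctrl_ind = np.array(
            [
                1.0 if count_annotation_overlaps(c, annotations) > 0 else 0.0
                for cset in control_sets
                for c in cset
            ]
        )
        n_real = int(real_ind.sum())
        return _t_result(
            real_ind,
            ctrl_ind,
            tails=1,
            equal_var=True,
            direction="greater",
            name=T_ONE_TAILED,
            effect=(
                f"real {n_real}/{len(real_ind)} loci overlap an annotation vs "
                f"pooled control {int(ctrl_ind.sum())}/{len(ctrl_ind)}"
            ),
        )
    if mode == "per_set":
        real_count = float(real_ind.sum())
        ctrl_counts = np.array(
            [
                float(
                    sum(
                        1.0
                        for c in cset
                        if count_annotation_overlaps(c, annotations) > 0
                    )
                )
                for cset in control_sets
            ]
        )
        flags: List[str] = ["per_set_mode"]
        if np.var(ctrl_counts, ddof=1) == 0:
            flags.append("degenerate_zero_variance")
            t, p = 0.0, 0.5 if real_count == ctrl_counts[0] else 0.0
            if real_count < ctrl_counts[0]:
                p = 1.0
            df = float(len(ctrl_counts) - 1)
        else:
            res = stats.ttest_1samp(
                ctrl_counts, real_count, alternative="less"
            )
            t, p = -float(res.statistic), float(res.pvalue)
            df = float(len(ctrl_counts) - 1)
        return EnrichmentResult(
            statistic_name=T_ONE_TAILED,
            statistic=t,
            df=df,
            p_value=p,
            effect_summary=(
                f"real count {real_count:g} vs control mean "
                f"{float(ctrl_counts.mean()):g}"
            ),
            flags=tuple(flags),
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Chi-square promoter G-triplet enrichment
# ---------------------------------------------------------------------------

def chi_square_triplet_enrichment(
    group_a: Sequence[PromoterRecord],
    group_b: Sequence[PromoterRecord],
    table_units: str = "slot",
    yates: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square comparing G-triplet content of two promoter groups.

    The 2x2 table is [motif units, non-motif units] x [group A, group B].
    With ``table_units="slot"`` (default) the unit is one 3-bp triplet
    slot: ``[count, floor(total_bp / 3) - count]``.  ``table_units="bp"``
    uses raw base-pair occupancy (each motif contributes 3 bp), which
    scales every cell — and the statistic — threefold.  No continuity
    correction unless ``yates=True``.  Expected cells below 5 are flagged.
    """
    if not group_a or not group_b:
        raise ValueError("both promoter groups must be non-empty")

    def _tally(group: Sequence[PromoterRecord]) -> Tuple[int, int]:
        count = sum(p.triplet_count_total for p in group)
        total_bp = sum(2 * len(p.window) for p in group)  # both strands
        return count, total_bp

    ca, bpa = _tally(group_a)
    cb, bpb = _tally(group_b)
    if table_units == "slot":
        table = np.array(
            [[ca, bpa // 3 - ca], [cb, bpb // 3 - cb]], dtype=float
        )
    elif table_units == "bp":
        table = np.array(
            [[3 * ca, bpa - 3 * ca], [3 * cb, bpb - 3 * cb]], dtype=float
        )
    else:
        raise ValueError(f"unknown table_units {table_units!r}")
    return chi_square_from_table(table, yates=yates)


def chi_square_from_table(
    table: np.ndarray, yates: bool = False
) -> EnrichmentResult:
    """Pearson chi-square on a 2x2 table (no continuity correction default)."""
    table = np.asarray(table, dtype=float)
    flags: List[str] = []
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    expected = np.outer(row, col) / total
    if (expected < 5).any():
        flags.append("low_expected_count")
    if np.isclose(expected, table).all():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)[:4]
    fold = (
        (table[0, 0] / row[0]) / (table[1, 0] / row[1])
        if table[1, 0] > 0 and row[0] > 0
        else float("nan")
    )
    return EnrichmentResult(
        statistic_name=CHI_SQUARE,
        statistic=float(chi2),
        df=1.0,
        p_value=float(p),
        effect_summary=f"proportion fold-change = {fold:.6g}",
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Fusion neighborhood test
# ---------------------------------------------------------------------------

def intra_neighborhood_fusion_count(
    neighborhood: Set[str], fusion_pairs: Iterable[Tuple[str, str]]
) -> int:
    """Fusion pairs with both partners inside one gene neighborhood."""
    return sum(1 for a, b in fusion_pairs if a in neighborhood and b in neighborhood)


def fusion_neighborhood_test(
    neighborhood_genes: Sequence[Set[str]],
    fusion_pairs: Sequence[Tuple[str, str]],
    control_neighborhood_genes: Sequence[Set[str]],
) -> EnrichmentResult:
    """Two-tailed t-test of intra-neighborhood fusion counts, real vs control."""
    real = np.array(
        [
            float(intra_neighborhood_fusion_count(n, fusion_pairs))
            for n in neighborhood_genes
        ]
    )
    ctrl = np.array(
        [
            float(intra_neighborhood_fusion_count(n, fusion_pairs))
            for n in control_neighborhood_genes
        ]
    )
    res = _t_result(
        real, ctrl, tails=2, equal_var=True, name=T_TWO_TAILED,
        effect=(
            f"mean intra-neighborhood fusions: real {real.mean():.3g} vs "
            f"control {ctrl.mean():.3g}"
        ),
    )
    if not fusion_pairs:
        res = EnrichmentResult(
            statistic_name=res.statistic_name,
            statistic=0.0,
            df=res.df,
            p_value=1.0,
            effect_summary=res.effect_summary,
            flags=tuple(set(res.flags) | {"degenerate_no_fusions"}),
        )
    return res
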