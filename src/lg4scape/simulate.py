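"""Synthetic genomes, annotations and Pore-C concatemer reads.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without downloads:

* a genomic background of i.i.d. bases at a controlled GC fraction, whose
  both-strand GGG-repeat density stays well below the LG4 calling
  threshold (about 24 repeats/kb at GC 0.5, versus the 80/kb criterion);
* planted LG4 loci, either exact short-unit repeats (``"GGGT" x 500``
  gives a 2000 bp block at exactly 250 repeats/kb) or aperiodic "mosaic"
  blocks of GGG triplets with random 1-7 bp non-G spacers (about 140
  repeats/kb) whose k-mers are effectively unique, so fragments drawn from
  them align unambiguously;
* promoter upstream windows carrying an exact number of isolated GGG
  tracts on the plus strand (the window background is scrubbed of
  incidental plus-strand GGG runs, and every planted tract is flanked by
  non-G guards, so the planted count is exact under either counting mode);
* verbatim duplications for exercising multi-map masking and tie-breaking;
* Pore-C reads formed by DpnII (GATC) digestion and proximity-biased
  concatemerization: a contact-bearing read carries one fragment from an
  LG4 and one from a cognate promoter window plus local filler fragments;
  background reads sample all fragments from one random neighborhood.

Everything is driven by a single integer seed per spec; identical
spec + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .enrichment import PromoterRecord, count_window_triplets
from .intervals import (
    Genome,
    GenomicInterval,
    MINUS,
    PLUS,
    UpstreamWindow,
    overlaps,
    resolve_window,
    reverse_complement,
)
from .porec import FragmentTruth, PoreCRead, ReadTruth

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
_NON_G = np.array([b"A", b"C", b"T"], dtype="S1")


@dataclass(frozen=True)
class PlantedLG4:
    """A planted high-GGG-density block.

    ``kind="repeat"`` writes ``unit * n_units`` verbatim; ``kind="mosaic"``
    writes ``length`` bp of GGG tracts with seeded random 1-7 bp non-G
    spacers (aperiodic, hence unambiguous to align).
    """

    chrom: str
    start: int
    unit: str = "GGGT"
    n_units: int = 500
    kind: str = "repeat"
    length: Optional[int] = None

    @property
    def span(self) -> GenomicInterval:
        n = self.length if self.kind == "mosaic" else len(self.unit) * self.n_units
        return GenomicInterval(self.chrom, self.start, self.start + n - 1)


@dataclass(frozen=True)
class PlantedPromoter:
    gene: str
    chrom: str
    tss: int
    strand: str = PLUS
    planted_triplets: int = 100
    window_bp: int = 5000

    @property
    def window(self) -> GenomicInterval:
        win = UpstreamWindow(self.gene, self.tss, self.strand, self.window_bp)
        if self.strand == MINUS:
            return GenomicInterval(self.chrom, self.tss + 1, self.tss + self.window_bp)
        return GenomicInterval(self.chrom, self.tss - self.window_bp, self.tss - 1)


@dataclass(frozen=True)
class PlantedDuplication:
    source: GenomicInterval
    n_copies: int = 1


@dataclass(frozen=True)
class PlantedGCBlock:
    """A GC-shifted background block (no G4 structure).

    Gives an otherwise homogeneous background genome regions of elevated
    (or depressed) GC, so composition-matched controls for GC-rich query
    loci have somewhere to land.  Plus-strand GGG runs are scrubbed, so
    the block never creates spurious LG4 signal at moderate GC.
    """

    chrom: str
    start: int
    length: int
    gc: float

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.start + self.length - 1)


@dataclass(frozen=True)
class GenomeSpec:
    """Declarative description of a synthetic genome."""

    chrom_lengths: Dict[str, int]
    background_gc: float = 0.5
    planted_lg4s: Tuple[PlantedLG4, ...] = ()
    planted_promoters: Tuple[PlantedPromoter, ...] = ()
    planted_duplications: Tuple[PlantedDuplication, ...] = ()
    planted_gc_blocks: Tuple[PlantedGCBlock, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth annotations of a generated genome."""

    lg4s: Tuple[Tuple[str, GenomicInterval], ...]  # (lg4_id, interval)
    promoters: Tuple[PlantedPromoter, ...]
    duplications: Tuple[Tuple[GenomicInterval, GenomicInterval], ...]


def _check_planted_layout(spec: GenomeSpec) -> List[GenomicInterval]:
    intervals: List[GenomicInterval] = []
    for lg4 in spec.planted_lg4s:
        intervals.append(lg4.span)
    for prom in spec.planted_promoters:
        intervals.append(prom.window)
    for dup in spec.planted_duplications:
        intervals.append(dup.source)
    for block in spec.planted_gc_blocks:
        intervals.append(block.span)
    for iv in intervals:
        if iv.chrom not in spec.chrom_lengths:
            raise ValueError(f"planted element on unknown chromosome {iv.chrom}")
        if iv.end > spec.chrom_lengths[iv.chrom]:
            raise ValueError(f"planted element {iv} exceeds chromosome length")
    for i, a in enumerate(intervals):
        for b in intervals[i + 1 :]:
            if overlaps(a, b):
                raise ValueError(f"planted elements overlap: {a} vs {b}")
    return intervals


def _scrub_plus_ggg(chars: np.ndarray, rng: np.random.Generator) -> None:
    """Break every plus-strand GGG run in-place (third G -> non-G draw)."""
    i, n = 2, len(chars)
    while i < n:
        if chars[i] == b"G" and chars[i - 1] == b"G" and chars[i - 2] == b"G":
            chars[i] = rng.choice(_NON_G)
        i += 1


def _mosaic_block(rng: np.random.Generator, length: int) -> str:
    parts: List[str] = []
    total = 0
    while total < length:
        parts.append("GGG")
        total += 3
        spacer_len = int(rng.integers(1, 8))
        spacer = "".join(
            rng.choice(_NON_G, size=spacer_len).astype("U1")
        )
        parts.append(spacer)
        total += spacer_len
    return "".join(parts)[:length]


def make_genome(spec: GenomeSpec) -> Tuple[Genome, SyntheticTruth]:
    """Generate a genome with its ground-truth annotations.

    Raises before generation if planted elements overlap or do not fit.
    """
    _check_planted_layout(spec)
    rng = np.random.default_rng(spec.seed)
    gc = spec.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    chrom_chars: Dict[str, np.ndarray] = {}
    for chrom in spec.chrom_lengths:
        n = spec.chrom_lengths[chrom]
        chrom_chars[chrom] = rng.choice(_BASES, size=n, p=probs)

    # GC-shifted background blocks (scrubbed of plus-strand GGG runs)
    for block in spec.planted_gc_blocks:
        bprobs = [
            (1 - block.gc) / 2,
            block.gc / 2,
            block.gc / 2,
            (1 - block.gc) / 2,
        ]
        bchars = rng.choice(_BASES, size=block.length, p=bprobs)
        _scrub_plus_ggg(bchars, rng)
        span = block.span
        chrom_chars[block.chrom][span.start - 1 : span.end] = bchars

    # promoter windows: scrub background GGG, then plant isolated tracts
    for prom in spec.planted_promoters:
        win = prom.window
        chars = chrom_chars[prom.chrom]
        wslice = chars[win.start - 1 : win.end]
        _scrub_plus_ggg(wslice, rng)
        n_slots = len(wslice) // 5
        if prom.planted_triplets > n_slots:
            raise ValueError(
                f"{prom.gene}: cannot fit {prom.planted_triplets} isolated "
                f"triplets in a {len(wslice)} bp window"
            )
        slots = rng.choice(n_slots, size=prom.planted_triplets, replace=False)
        for s in np.sort(slots):
            off = int(s) * 5
            if wslice[off] == b"G":
                wslice[off] = rng.choice(_NON_G)
            wslice[off + 1 : off + 4] = b"G"
            if wslice[off + 4] == b"G":
                wslice[off + 4] = rng.choice(_NON_G)

    # planted LG4 blocks
    lg4_truth: List[Tuple[str, GenomicInterval]] = []
    for idx, lg4 in enumerate(spec.planted_lg4s):
        span = lg4.span
        if lg4.kind == "repeat":
            block = (lg4.unit * lg4.n_units).upper()
        elif lg4.kind == "mosaic":
            if lg4.length is None:
                raise ValueError("mosaic LG4 needs an explicit length")
            block = _mosaic_block(rng, lg4.length)
        else:
            raise ValueError(f"unknown planted LG4 kind {lg4.kind!r}")
        arr = np.frombuffer(block.encode(), dtype="S1")
        chrom_chars[lg4.chrom][span.start - 1 : span.end] = arr
        lg4_truth.append((f"LG4_{idx + 1}", span))

    genome = Genome(
        {c: chars.tobytes().decode() for c, chars in chrom_chars.items()}
    )

    # duplications copied verbatim after all planting, to seeded random slots
    dup_truth: List[Tuple[GenomicInterval, GenomicInterval]] = []
    occupied = _check_planted_layout(spec)
    if spec.planted_duplications:
        for dup in spec.planted_duplications:
            text = genome.fetch(
                GenomicInterval(dup.source.chrom, dup.source.start, dup.source.end)
            )
            dlen = len(text)
            for _copy in range(dup.n_copies):
                placed = None
                for _try in range(1000):
                    chrom = list(spec.chrom_lengths)[
                        int(rng.integers(0, len(spec.chrom_lengths)))
                    ]
                    clen = spec.chrom_lengths[chrom]
                    if clen < dlen:
                        continue
                    start = int(rng.integers(1, clen - dlen + 2))
                    cand = GenomicInterval(chrom, start, start + dlen - 1)
                    if any(overlaps(cand, iv) for iv in occupied):
                        continue
                    if any(overlaps(cand, t) for _s, t in dup_truth):
                        continue
                    placed = cand
                    break
                if placed is None:
                    raise RuntimeError(
                        f"could not place duplication copy of {dup.source}"
                    )
                chrom_chars[placed.chrom][
                    placed.start - 1 : placed.end
                ] = np.frombuffer(text.encode(), dtype="S1")
                dup_truth.append((dup.source, placed))
        genome = Genome(
            {c: chars.tobytes().decode() for c, chars in chrom_chars.items()}
        )

    truth = SyntheticTruth(
        lg4s=tuple(lg4_truth),
        promoters=tuple(spec.planted_promoters),
        duplications=tuple(dup_truth),
    )
    return genome, truth


def truth_promoter_records(
    genome: Genome, truth: SyntheticTruth
) -> List[PromoterRecord]:
    """Recount triplet content of the planted promoters from the sequence."""
    return [
        count_window_triplets(
            p.gene, p.chrom, p.tss, p.strand, genome, window_bp=p.window_bp
        )
        for p in truth.promoters
    ]


# ---------------------------------------------------------------------------
# Restriction digestion
# ---------------------------------------------------------------------------

def digest_genome(
    genome: Genome, site: str = "GATC"
) -> Dict[str, List[GenomicInterval]]:
    """DpnII-style digestion: one cut immediately 5' of each site.

    Fragments tile each chromosome exactly; a chromosome with no site is a
    single fragment.
    """
    if not site:
        raise ValueError("site must be non-empty")
    out: Dict[str, List[GenomicInterval]] = {}
    for chrom in genome:
        seq = genome.sequence(chrom)
        cuts = []
        pos = seq.find(site)
        while pos != -1:
            cuts.append(pos + 1)  # 1-based position of site start
            pos = seq.find(site, pos + 1)
        frags: List[GenomicInterval] = []
        prev = 1
        for c in cuts:
            if c > prev:
                frags.append(GenomicInterval(chrom, prev, c - 1))
                prev = c
        frags.append(GenomicInterval(chrom, prev, len(seq)))
        out[chrom] = frags
    return out


# ---------------------------------------------------------------------------
# Pore-C read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactModel:
    """Parameters of the concatemer read simulator.

    ``contact_pairs`` lists (lg4_id, gene, probability); for each read the
    pairs are tried in order and the first Bernoulli success makes the
    read contact-bearing for that pair.  Fragments per read are uniform on
    ``fragments_per_read`` (inclusive); filler fragments come from within
    ``neighborhood_bp`` of a contact anchor (or of a random anchor for
    background reads), mimicking insulated-neighborhood locality without a
    polymer model.  Errors are substitutions only.
    """

    contact_pairs: Tuple[Tuple[str, str, float], ...]
    n_reads: int = 100
    fragments_per_read: Tuple[int, int] = (3, 12)
    substitution_rate: float = 0.0
    neighborhood_bp: int = 250_000
    min_fragment_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for lid, gene, p in self.contact_pairs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1] for {lid}:{gene}")
        if self.fragments_per_read[0] < 2:
            raise ValueError("contact-capable reads need >= 2 fragments")


def _substitute(
    chars: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return chars
    hit = rng.random(len(chars)) < rate
    if hit.any():
        chars = chars.copy()
        # replace with a uniformly drawn *different* base
        for i in np.flatnonzero(hit):
            alts = _BASES[_BASES != chars[i]]
            chars[i] = alts[int(rng.integers(0, len(alts)))]
    return chars


def simulate_porec(
    genome: Genome,
    digest: Dict[str, List[GenomicInterval]],
    truth: SyntheticTruth,
    model: ContactModel,
) -> List[PoreCRead]:
    """Simulate concatemer reads with full per-fragment provenance.

    Each read's truth records every fragment's source interval (with the
    sampled strand) and the read's *realized* contact pairs: the pairs for
    which the assembled read actually contains one LG4-overlapping and one
    distinct promoter-window-overlapping fragment.  Realized status is a
    superset of the Bernoulli intent, so downstream recovery can be
    compared against it exactly.
    """
    rng = np.random.default_rng(model.seed)
    lg4_by_id = dict(truth.lg4s)
    prom_by_gene = {p.gene: p for p in truth.promoters}

    usable = [
        f
        for frags in digest.values()
        for f in frags
        if len(f) >= model.min_fragment_length
    ]
    if not usable:
        raise ValueError("no digest fragments pass min_fragment_length")

    pair_anchors: List[Tuple[str, str, float, List, List]] = []
    for lid, gene, p in model.contact_pairs:
        if lid not in lg4_by_id:
            raise ValueError(f"unknown LG4 id {lid!r} in contact model")
        if gene not in prom_by_gene:
            raise ValueError(f"unknown promoter gene {gene!r} in contact model")
        liv = lg4_by_id[lid]
        wiv = prom_by_gene[gene].window
        lfr = [f for f in usable if overlaps(f, liv)]
        pfr = [f for f in usable if overlaps(f, wiv)]
        if not lfr or not pfr:
            raise ValueError(
                f"pair {lid}:{gene} has no usable digest fragments"
            )
        pair_anchors.append((lid, gene, p, lfr, pfr))

    def _neighborhood(anchor: GenomicInterval) -> List[GenomicInterval]:
        lo = anchor.start - model.neighborhood_bp
        hi = anchor.end + model.neighborhood_bp
        return [
            f
            for f in usable
            if f.chrom == anchor.chrom and f.start <= hi and f.end >= lo
        ]

    reads: List[PoreCRead] = []
    fmin, fmax = model.fragments_per_read
    for ridx in range(model.n_reads):
        nfrag = int(rng.integers(fmin, fmax + 1))
        chosen: List[GenomicInterval] = []
        intended: Optional[Tuple[str, str]] = None
        for lid, gene, p, lfr, pfr in pair_anchors:
            if rng.random() < p:
                intended = (lid, gene)
                anchor_l = lfr[int(rng.integers(0, len(lfr)))]
                anchor_p = pfr[int(rng.integers(0, len(pfr)))]
                chosen = [anchor_l, anchor_p]
                pool = _neighborhood(anchor_l) + _neighborhood(anchor_p)
                for _ in range(nfrag - 2):
                    chosen.append(pool[int(rng.integers(0, len(pool)))])
                break
        if intended is None:
            anchor = usable[int(rng.integers(0, len(usable)))]
            pool = _neighborhood(anchor)
            chosen = [pool[int(rng.integers(0, len(pool)))] for _ in range(nfrag)]

        order = rng.permutation(len(chosen))
        parts: List[str] = []
        frag_truth: List[FragmentTruth] = []
        for j in order:
            frag = chosen[int(j)]
            strand = PLUS if rng.random() < 0.5 else MINUS
            seq = genome.fetch(
                GenomicInterval(frag.chrom, frag.start, frag.end, strand)
            )
            chars = np.frombuffer(seq.encode(), dtype="S1")
            chars = _substitute(chars, model.substitution_rate, rng)
            parts.append(chars.tobytes().decode())
            frag_truth.append(
                FragmentTruth(
                    GenomicInterval(frag.chrom, frag.start, frag.end, strand)
                )
            )

        realized: List[Tuple[str, str]] = []
        for lid, gene, _p, _lfr, _pfr in pair_anchors:
            liv = lg4_by_id[lid]
            wiv = prom_by_gene[gene].window
            l_idx = {
                i for i, ft in enumerate(frag_truth) if overlaps(ft.source, liv)
            }
            p_idx = {
                i for i, ft in enumerate(frag_truth) if overlaps(ft.source, wiv)
            }
            if l_idx and (p_idx - l_idx):
                realized.append((lid, gene))

        reads.append(
            PoreCRead(
                read_id=f"simread_{ridx + 1}",
                sequence="".join(parts),
                truth=ReadTruth(
                    fragments=tuple(frag_truth),
                    contact_pairs=tuple(realized),
                    intended_pair=intended,
                ),
            )
        )
    return reads
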