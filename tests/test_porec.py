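"""Masking, fragment alignment, best-hit resolution and contact calling."""

import numpy as np
import pytest

from lg4scape import (
    FragmentAlignment,
    GenomeSpec,
    GenomicInterval,
    PlantedDuplication,
    PoreCRead,
    align_read_fragments,
    align_reads,
    contact_summary,
    detect_cooccurrence,
    make_genome,
    mask_multimapping,
    resolve_best,
    simulate_porec,
)
from lg4scape.enrichment import PromoterRecord
from lg4scape.porec import ContactRecord
from conftest import contact_model


@pytest.fixture(scope="module")
def dup_world():
    spec = GenomeSpec(
        chrom_lengths={"c1": 30_000, "c2": 30_000},
        planted_duplications=(
            PlantedDuplication(GenomicInterval("c1", 5001, 5150), 1),
        ),
        seed=3,
    )
    return make_genome(spec)


# ---------------------------------------------------------------------------
# multi-map masking
# ---------------------------------------------------------------------------

def test_mask_planted_duplication(dup_world):
    genome, truth = dup_world
    prom = genome.fetch(GenomicInterval("c1", 4901, 5250))  # dup at local 101..250
    (_pid, masked), = mask_multimapping([("p1", prom)], genome, min_len=100)
    assert set(masked[100:250]) == {"N"}  # the whole planted block is masked
    # flanks (away from any coincidental extension of the repeat) intact
    assert "N" not in masked[:95]
    assert "N" not in masked[260:]


def test_mask_leaves_unique_sequence_unchanged(dup_world):
    genome, _ = dup_world
    prom = genome.fetch(GenomicInterval("c2", 1001, 1500))
    (_pid, masked), = mask_multimapping([("p", prom)], genome, min_len=100)
    assert masked == prom


def test_mask_boundary_exactly_min_len_unmasked():
    """A duplicated stretch of exactly min_len bp is below the '>' rule."""
    spec = GenomeSpec(
        chrom_lengths={"c1": 30_000, "c2": 30_000},
        planted_duplications=(
            PlantedDuplication(GenomicInterval("c1", 5001, 5100), 1),
        ),
        seed=4,
    )
    genome, truth = dup_world_exact = make_genome(spec)
    # the duplicated block plus flanks: only >100 bp duplicates get masked
    prom = genome.fetch(GenomicInterval("c1", 4951, 5150))
    (_pid, masked), = mask_multimapping([("p", prom)], genome, min_len=100)
    assert masked == prom


# ---------------------------------------------------------------------------
# alignment scoring
# ---------------------------------------------------------------------------

def test_verbatim_slice_scores_two_per_base(dup_world):
    genome, _ = dup_world
    read = PoreCRead("r", genome.fetch(GenomicInterval("c2", 10_001, 10_500)))
    (aln,) = align_read_fragments(read, genome)
    assert aln.score == 1000
    assert aln.n_equal_best == 1 and not aln.is_ambiguous
    assert (aln.target.chrom, aln.target.start, aln.target.end) == (
        "c2", 10_001, 10_500,
    )
    assert (aln.read_start, aln.read_end) == (1, 500)


def test_single_internal_substitution_costs_five(dup_world):
    genome, _ = dup_world
    seq = list(genome.fetch(GenomicInterval("c2", 10_001, 10_500)))
    seq[250] = "C" if seq[250] != "C" else "A"
    (aln,) = align_read_fragments(PoreCRead("r", "".join(seq)), genome)
    assert aln.score == 2 * 499 - 3  # 995


def test_minus_strand_fragment_recovered(dup_world):
    genome, _ = dup_world
    read = PoreCRead(
        "r", genome.fetch(GenomicInterval("c2", 10_001, 10_400, "-"))
    )
    (aln,) = align_read_fragments(read, genome)
    assert aln.target.strand == "-"
    assert (aln.target.start, aln.target.end) == (10_001, 10_400)


def test_duplicated_fragment_is_ambiguous(dup_world):
    genome, truth = dup_world
    src, copy = truth.duplications[0]
    read = PoreCRead("r", genome.fetch(GenomicInterval(src.chrom, src.start, src.end)))
    (aln,) = align_read_fragments(read, genome)
    assert aln.n_equal_best == 2
    assert aln.is_ambiguous
    # lowest-coordinate tie rule
    low = min([src, copy], key=lambda iv: (iv.chrom, iv.start))
    assert (aln.target.chrom, aln.target.start) == (low.chrom, low.start)


def test_short_read_empty(dup_world):
    genome, _ = dup_world
    assert align_read_fragments(PoreCRead("r", "ACGTACGT"), genome) == []


# ---------------------------------------------------------------------------
# best-hit resolution
# ---------------------------------------------------------------------------

def _cand(chrom, start, score, read_id="r", span=(1, 500)):
    return FragmentAlignment(
        read_id, span[0], span[1],
        GenomicInterval(chrom, start, start + span[1] - span[0]), score,
    )


def test_resolve_best_highest_score_wins():
    got = resolve_best([_cand("c2", 500, 990), _cand("c1", 900, 1000)])
    assert got.score == 1000 and got.target.chrom == "c1"
    assert not got.is_ambiguous


def test_resolve_best_tie_lowest_coordinate():
    got = resolve_best([_cand("c2", 500, 1000), _cand("c1", 900, 1000)])
    assert (got.target.chrom, got.target.start) == ("c1", 900)
    assert got.is_ambiguous and got.n_equal_best == 2


def test_resolve_best_matches_bruteforce_oracle():
    rng = np.random.default_rng(77)
    for _ in range(200):
        n = int(rng.integers(1, 8))
        cands = [
            _cand(
                f"c{int(rng.integers(1, 4))}",
                int(rng.integers(1, 10_000)),
                int(rng.integers(90, 96)) * 10,
            )
            for _ in range(n)
        ]
        got = resolve_best(cands)
        best = max(c.score for c in cands)
        oracle = sorted(
            (c for c in cands if c.score == best),
            key=lambda c: (c.target.chrom, c.target.start),
        )[0]
        assert (got.target.chrom, got.target.start, got.score) == (
            oracle.target.chrom, oracle.target.start, oracle.score,
        )
        assert got.n_equal_best == sum(1 for c in cands if c.score == best)


# ---------------------------------------------------------------------------
# contact calling
# ---------------------------------------------------------------------------

def _prom(gene, chrom, lo, hi):
    return PromoterRecord(
        gene, chrom, hi + 1, "+", GenomicInterval(chrom, lo, hi), 0, 0
    )


def test_contact_by_definition():
    lg4 = [("L1", GenomicInterval("c", 1000, 2000))]
    prom = [_prom("gA", "c", 50_000, 55_000)]
    al = {
        "read1": [
            _cand("c", 1500, 400, "read1", span=(1, 200)),
            _cand("c", 51_000, 400, "read1", span=(301, 500)),
        ]
    }
    contacts = detect_cooccurrence(al, lg4, prom)
    assert len(contacts) == 1
    assert contacts[0].lg4_id == "L1" and contacts[0].promoter_gene == "gA"


def test_two_lg4_fragments_no_promoter_no_contact():
    lg4 = [("L1", GenomicInterval("c", 1000, 2000))]
    al = {
        "r": [
            _cand("c", 1100, 400, "r", span=(1, 200)),
            _cand("c", 1500, 400, "r", span=(301, 500)),
        ]
    }
    assert detect_cooccurrence(al, lg4, [_prom("gA", "c", 50_000, 55_000)]) == []


def test_ambiguous_fragments_excluded_by_default():
    lg4 = [("L1", GenomicInterval("c", 1000, 2000))]
    prom = [_prom("gA", "c", 50_000, 55_000)]
    amb = FragmentAlignment(
        "r", 1, 200, GenomicInterval("c", 1500, 1699), 400,
        n_equal_best=2, is_ambiguous=True,
    )
    al = {"r": [amb, _cand("c", 51_000, 400, "r", span=(301, 500))]}
    assert detect_cooccurrence(al, lg4, prom) == []
    assert len(detect_cooccurrence(al, lg4, prom, include_ambiguous=True)) == 1


def test_contact_record_rejects_overlapping_spans():
    with pytest.raises(ValueError):
        ContactRecord(
            "r", "L1", "gA",
            _cand("c", 1500, 400, "r", span=(1, 300)),
            _cand("c", 51_000, 400, "r", span=(250, 500)),
        )


def test_truth_closure_error_free(contact_world, simulated_reads_err0):
    """At zero error the detected contact-read pair sets equal the truth."""
    reads = simulated_reads_err0
    al = align_reads(reads, contact_world["index"])
    contacts = detect_cooccurrence(
        al, contact_world["truth"].lg4s, contact_world["promoters"]
    )
    detected = {}
    for c in contacts:
        detected.setdefault(c.read_id, set()).add((c.lg4_id, c.promoter_gene))
    expected = {
        r.read_id: set(r.truth.contact_pairs)
        for r in reads
        if r.truth.contact_pairs
    }
    assert detected == expected
    # and no record pairs overlapping read spans
    for c in contacts:
        assert not (
            c.lg4_fragment.read_start <= c.promoter_fragment.read_end
            and c.promoter_fragment.read_start <= c.lg4_fragment.read_end
        )


def test_fragment_recovery_at_zero_error(contact_world, simulated_reads_err0):
    """Every fragment resolves to its source, boundaries within word size.

    Boundary jitter up to the seed word size can arise when a neighbouring
    segment's extension bled across the ligation junction and the true
    owner was clipped; the placement itself must still be the source locus.
    """
    al = align_reads(simulated_reads_err0[:100], contact_world["index"])
    checked = 0
    for read in simulated_reads_err0[:100]:
        placements = [
            a.target for a in al[read.read_id] if not a.is_ambiguous
        ]
        for ft in read.truth.fragments:
            src = ft.source
            hit = any(
                t.chrom == src.chrom
                and min(t.end, src.end) - max(t.start, src.start) + 1
                >= 0.9 * len(src)
                for t in placements
            )
            assert hit, (read.read_id, str(src), [str(t) for t in placements])
            checked += 1
    assert checked > 100


def test_sensitivity_at_5pct_substitution(contact_world):
    """>= 90% of 300+ bp fragments still place correctly at 5% error."""
    reads = simulate_porec(
        contact_world["genome"],
        contact_world["digest"],
        contact_world["truth"],
        contact_model(seed=61, n_reads=150, rate=0.05),
    )
    al = align_reads(reads, contact_world["index"])
    total = correct = 0
    for read in reads:
        placements = [
            (a.target.chrom, a.target.start, a.target.end)
            for a in al[read.read_id]
        ]
        for ft in read.truth.fragments:
            if len(ft.source) < 300:
                continue
            total += 1
            hit = any(
                c == ft.source.chrom
                and s <= ft.source.end
                and e >= ft.source.start
                and min(e, ft.source.end) - max(s, ft.source.start) + 1
                >= 0.8 * len(ft.source)
                for c, s, e in placements
            )
            correct += int(hit)
    assert total > 200
    assert correct / total >= 0.90


def test_contact_summary_counts_distinct_reads():
    assert contact_summary([]).empty
    lg4f = _cand("c", 1500, 400, "r1", span=(1, 200))
    promf = _cand("c", 51_000, 400, "r1", span=(301, 500))
    def rec(rid):
        return ContactRecord(
            rid, "L1", "gA",
            _cand("c", 1500, 400, rid, span=(1, 200)),
            _cand("c", 51_000, 400, rid, span=(301, 500)),
        )
    df = contact_summary([rec("r1"), rec("r1"), rec("r2")])
    assert df.iloc[0].to_dict() == {
        "lg4_id": "L1", "promoter_gene": "gA", "n_reads": 2,
    }
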