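"""Matched controls and the enrichment statistics against formula oracles."""

import math

import numpy as np
import pytest

from lg4scape import (
    EnhancerAnnotation,
    Genome,
    GenomeSpec,
    GenomicInterval,
    PlantedGCBlock,
    PlantedPromoter,
    chi_square_from_table,
    chi_square_triplet_enrichment,
    count_annotation_overlaps,
    count_window_triplets,
    fusion_neighborhood_test,
    make_genome,
    matched_control_loci,
    overlap_enrichment_test,
    welch_t_test,
)
from lg4scape.enrichment import PromoterRecord
from lg4scape.verify import CHR12_LG4, CHR5_LG4, load_table1
from conftest import random_dna


def _record(gene, plus, minus, wlen=5000):
    return PromoterRecord(
        gene, "c", wlen + 1, "+", GenomicInterval("c", 1, wlen), plus, minus
    )


# ---------------------------------------------------------------------------
# promoter window counting
# ---------------------------------------------------------------------------

def test_count_window_triplets_small_example():
    seq = "GGGAAACCC" + "A" * 4991 + "T"  # TSS at 5001, window covers first 5 kb
    g = Genome({"c": seq})
    rec = count_window_triplets("g", "c", 5001, "+", g)
    assert rec.triplet_count_plus == 1
    assert rec.triplet_count_minus == 1
    assert rec.triplet_count_total == 2
    assert not rec.truncated


def test_count_window_triplets_all_a():
    g = Genome({"c": "A" * 6000})
    rec = count_window_triplets("g", "c", 5001, "+", g)
    assert rec.triplet_count_total == 0


def test_count_window_triplets_truncated_flag():
    g = Genome({"c": "A" * 6000})
    rec = count_window_triplets("g", "c", 3000, "+", g)
    assert rec.truncated
    assert len(rec.window) == 2999


def test_planted_237_recovered():
    """A promoter planted with 237 isolated tracts recounts to exactly 237."""
    spec = GenomeSpec(
        chrom_lengths={"c": 20_000},
        planted_promoters=(PlantedPromoter("EX", "c", 10_000, "+", 237),),
        seed=13,
    )
    genome, _ = make_genome(spec)
    rec = count_window_triplets("EX", "c", 10_000, "+", genome)
    assert rec.triplet_count_plus == 237


# ---------------------------------------------------------------------------
# matched controls
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def het_genome():
    spec = GenomeSpec(
        chrom_lengths={"c1": 60_000, "c2": 60_000},
        background_gc=0.5,
        planted_gc_blocks=(
            PlantedGCBlock("c1", 20_001, 8000, 0.62),
            PlantedGCBlock("c2", 30_001, 8000, 0.38),
        ),
        seed=17,
    )
    return make_genome(spec)[0]


def test_matched_controls_contract(het_genome):
    source = [GenomicInterval("c1", 5001, 6000)]
    gc = _gc(het_genome, source[0])
    sets = matched_control_loci(source, het_genome, n_sets=1, seed=17)
    ctrl = sets[0][0]
    assert len(ctrl) == 1000
    assert abs(_gc(het_genome, ctrl) - gc) <= 0.02
    assert not ctrl.overlaps(source[0])


def _gc(genome, iv):
    seq = genome.fetch(GenomicInterval(iv.chrom, iv.start, iv.end))
    return (seq.count("G") + seq.count("C")) / len(seq)


def test_matched_controls_100_seeded_draws_all_satisfy_tolerances(het_genome):
    source = [
        GenomicInterval("c1", 5001, 6000),
        GenomicInterval("c1", 21_001, 22_000),  # inside the GC-rich block
    ]
    gcs = [_gc(het_genome, s) for s in source]
    for seed in range(100):
        (ctrls,) = matched_control_loci(source, het_genome, n_sets=1, seed=seed)
        for src, gc, ctrl in zip(source, gcs, ctrls):
            assert len(ctrl) == len(src)
            assert abs(_gc(het_genome, ctrl) - gc) <= 0.02
            assert all(not ctrl.overlaps(s) for s in source)
        assert not ctrls[0].overlaps(ctrls[1])


def test_matched_controls_deterministic(het_genome):
    source = [GenomicInterval("c1", 5001, 6000)]
    a = matched_control_loci(source, het_genome, n_sets=3, seed=99)
    b = matched_control_loci(source, het_genome, n_sets=3, seed=99)
    assert a == b


def test_matched_controls_placement_failure_names_locus(het_genome):
    # GC 0.9 target is unreachable in this genome
    weird = Genome({"w": "G" * 2000 + "A" * 500})
    with pytest.raises(RuntimeError, match="w:1:2000"):
        matched_control_loci(
            [GenomicInterval("w", 1, 2000)], weird, n_sets=1, seed=1, max_tries=50
        )


# ---------------------------------------------------------------------------
# annotation overlap counting
# ---------------------------------------------------------------------------

def test_count_annotation_overlaps_reference_rows():
    anns = load_table1()
    assert count_annotation_overlaps(CHR5_LG4, anns) == 13
    assert count_annotation_overlaps(CHR12_LG4, anns) == 9
    assert count_annotation_overlaps(CHR5_LG4, []) == 0


def test_count_annotation_overlaps_is_sum_of_pairwise_overlaps():
    anns = load_table1()
    expected = sum(1 for a in anns if CHR5_LG4.overlaps(a.interval))
    assert count_annotation_overlaps(CHR5_LG4, anns) == expected


# ---------------------------------------------------------------------------
# overlap enrichment t-test
# ---------------------------------------------------------------------------

def _loci_with_indicators(indicators, chrom="t"):
    """Build loci + one annotation such that locus i overlaps iff indicators[i]."""
    loci = [
        GenomicInterval(chrom, 10_000 * (i + 1), 10_000 * (i + 1) + 99)
        for i in range(len(indicators))
    ]
    ann_iv = GenomicInterval(chrom, 1, 1)  # placeholder, replaced below
    hit_ivs = [l for l, ind in zip(loci, indicators) if ind]
    anns = [
        EnhancerAnnotation(f"a{i}", "ENCODE", iv)
        for i, iv in enumerate(hit_ivs)
    ]
    return loci, anns


def test_overlap_enrichment_strong_separation():
    real_ind = [1] * 19 + [0]  # one flipped to break zero variance
    ctrl_ind = [0] * 20
    real, anns = _loci_with_indicators(real_ind, chrom="r")
    ctrl, _ = _loci_with_indicators(ctrl_ind, chrom="z")
    res = overlap_enrichment_test(real, [ctrl[:10], ctrl[10:]], anns)
    assert res.p_value < 0.001
    assert res.statistic > 0


def test_overlap_enrichment_identical_groups_is_degenerate_midpoint():
    real, anns = _loci_with_indicators([0] * 10, chrom="r")
    ctrl, _ = _loci_with_indicators([0] * 10, chrom="r")
    res = overlap_enrichment_test(real, [ctrl[:5], ctrl[5:]], anns)
    assert res.statistic == 0.0
    assert res.p_value == 0.5
    assert "degenerate_zero_variance" in res.flags


def test_overlap_enrichment_matches_pooled_t_formula():
    """Indicators {1,1,1,0,1} vs {0,0,1,0,0} equal the hand-computed t."""
    a, b = [1, 1, 1, 0, 1], [0, 0, 1, 0, 0]
    real, anns_r = _loci_with_indicators(a, chrom="r")
    ctrl, anns_c = _loci_with_indicators(b, chrom="z")
    res = overlap_enrichment_test(real, [ctrl[:2], ctrl[2:]], anns_r + anns_c)
    xa, xb = np.array(a, float), np.array(b, float)
    sp2 = (
        ((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()
    ) / (len(a) + len(b) - 2)
    t_hand = (xa.mean() - xb.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    assert res.statistic == pytest.approx(t_hand)
    assert res.df == len(a) + len(b) - 2


def test_overlap_enrichment_per_set_mode():
    real, anns = _loci_with_indicators([1, 1, 1], chrom="r")
    ctrl1, _ = _loci_with_indicators([1, 0, 0], chrom="z")
    ctrl2, _ = _loci_with_indicators([0, 1, 0], chrom="z")
    ctrl3, _ = _loci_with_indicators([0, 0, 0], chrom="z")
    # control sets on chrom z never overlap annotations built on chrom r
    res = overlap_enrichment_test(
        real, [ctrl1, ctrl2, ctrl3], anns, mode="per_set"
    )
    assert "per_set_mode" in res.flags


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi_square_textbook_table():
    res = chi_square_from_table([[10, 90], [20, 80]])
    # Pearson formula oracle: sum (O-E)^2/E = 3.9216 to 4 s.f.
    assert res.statistic == pytest.approx(3.9216, abs=5e-5)
    assert res.df == 1


def test_chi_square_identical_groups_zero():
    a = [_record("a1", 50, 50), _record("a2", 40, 60)]
    res = chi_square_triplet_enrichment(a, list(a))
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_chi_square_symmetric_in_groups():
    a = [_record("a", 80, 70)]
    b = [_record("b", 30, 20)]
    assert chi_square_triplet_enrichment(a, b).statistic == pytest.approx(
        chi_square_triplet_enrichment(b, a).statistic
    )


def test_chi_square_planted_3x_density_detected():
    rng = np.random.default_rng(19)
    group_a = [
        _record(f"a{i}", int(rng.poisson(54)), int(rng.poisson(54)))
        for i in range(50)
    ]
    group_b = [
        _record(f"b{i}", int(rng.poisson(18)), int(rng.poisson(18)))
        for i in range(50)
    ]
    assert chi_square_triplet_enrichment(group_a, group_b).p_value < 0.01


def test_chi_square_bp_units_scale_statistic_threefold():
    a = [_record("a", 80, 70)]
    b = [_record("b", 30, 20)]
    slot = chi_square_triplet_enrichment(a, b, table_units="slot").statistic
    bp = chi_square_triplet_enrichment(a, b, table_units="bp").statistic
    assert bp == pytest.approx(3 * slot, rel=1e-3)


def test_chi_square_low_expected_flag():
    res = chi_square_from_table([[1, 30], [2, 40]])
    assert "low_expected_count" in res.flags


# ---------------------------------------------------------------------------
# fusion neighborhood test
# ---------------------------------------------------------------------------

def test_fusion_counts_trivial():
    from lg4scape.enrichment import intra_neighborhood_fusion_count

    assert intra_neighborhood_fusion_count({"A", "B", "C"}, [("A", "B")]) == 1
    assert intra_neighborhood_fusion_count({"A", "B", "C"}, [("A", "X")]) == 0


def test_fusion_empty_list_flagged_degenerate():
    res = fusion_neighborhood_test([{"A", "B"}], [], [{"C", "D"}])
    assert res.statistic == 0.0
    assert "degenerate_no_fusions" in res.flags


def test_fusion_planted_enrichment_detected():
    rng = np.random.default_rng(23)
    fusions = []
    real, ctrl = [], []
    for i in range(20):
        genes = {f"r{i}_{j}" for j in range(10)}
        real.append(genes)
        glist = sorted(genes)
        for _ in range(int(rng.poisson(3.0))):
            a, b = rng.choice(len(glist), size=2, replace=False)
            fusions.append((glist[int(a)], glist[int(b)]))
    for i in range(20):
        genes = {f"c{i}_{j}" for j in range(10)}
        ctrl.append(genes)
        glist = sorted(genes)
        for _ in range(int(rng.poisson(0.3))):
            a, b = rng.choice(len(glist), size=2, replace=False)
            fusions.append((glist[int(a)], glist[int(b)]))
    res = fusion_neighborhood_test(real, fusions, ctrl)
    assert res.p_value < 0.01
    assert res.statistic > 0


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def test_welch_identical_samples():
    res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0


def test_welch_matches_hand_formula():
    x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
    res = welch_t_test(x, y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se = math.sqrt(vx / 4 + vy / 4)
    t_hand = (np.mean(x) - np.mean(y)) / se
    df_hand = (vx / 4 + vy / 4) ** 2 / (
        (vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3
    )
    assert res.statistic == pytest.approx(t_hand)
    assert res.df == pytest.approx(df_hand)


def test_welch_p_close_to_permutation_null():
    rng = np.random.default_rng(29)
    x = rng.normal(0.9, 1.0, size=10)
    y = rng.normal(0.0, 1.0, size=10)
    res = welch_t_test(list(x), list(y))
    pooled = np.concatenate([x, y])
    obs = abs(res.statistic)
    n_perm, hits = 10_000, 0
    from scipy import stats as ss

    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = ss.ttest_ind(perm[:10], perm[10:], equal_var=False).statistic
        if abs(t) >= obs:
            hits += 1
    p_perm = hits / n_perm
    mc_se = math.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / n_perm)
    assert abs(res.p_value - p_perm) <= 0.02 + 3 * mc_se


def test_welch_zero_variance_degenerate():
    res = welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
    assert "degenerate_zero_variance" in res.flags
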