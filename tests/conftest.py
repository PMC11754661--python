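"""Shared synthetic worlds and helpers for the test suite.

All fixtures are seeded and deterministic; the heavier worlds (aligner
index, simulated read sets) are session-scoped so they are built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from lg4scape import (
    ContactModel,
    GenomeIndex,
    GenomeSpec,
    PlantedGCBlock,
    PlantedLG4,
    PlantedPromoter,
    digest_genome,
    make_genome,
    simulate_porec,
    truth_promoter_records,
)

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def contact_world_spec(seed: int) -> GenomeSpec:
    """Two mosaic LG4s and four promoters, anchors far enough apart that
    a +/-25 kb filler neighborhood can never span both ends of a pair."""
    return GenomeSpec(
        chrom_lengths={"chrA": 200_000, "chrB": 150_000},
        background_gc=0.5,
        planted_lg4s=(
            PlantedLG4("chrA", 30_001, kind="mosaic", length=4000),
            PlantedLG4("chrB", 20_001, kind="mosaic", length=3000),
        ),
        planted_promoters=(
            PlantedPromoter("EX1", "chrA", 120_000, "+", 220),
            PlantedPromoter("EX2", "chrA", 170_000, "+", 150),
            PlantedPromoter("EX3", "chrB", 100_000, "+", 180),
            PlantedPromoter("EX4", "chrB", 140_000, "+", 80),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def contact_world():
    genome, truth = make_genome(contact_world_spec(31))
    digest = digest_genome(genome)
    index = GenomeIndex(genome)
    promoters = truth_promoter_records(genome, truth)
    return {
        "genome": genome,
        "truth": truth,
        "digest": digest,
        "index": index,
        "promoters": promoters,
    }


def contact_model(seed: int, n_reads: int, rate: float = 0.0, pairs=None):
    return ContactModel(
        contact_pairs=pairs
        if pairs is not None
        else (("LG4_1", "EX1", 0.3), ("LG4_2", "EX3", 0.2)),
        n_reads=n_reads,
        fragments_per_read=(3, 8),
        substitution_rate=rate,
        neighborhood_bp=25_000,
        min_fragment_length=150,
        seed=seed,
    )


@pytest.fixture(scope="session")
def simulated_reads_err0(contact_world):
    reads = simulate_porec(
        contact_world["genome"],
        contact_world["digest"],
        contact_world["truth"],
        contact_model(seed=47, n_reads=500),
    )
    return reads
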