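"""Shared fixtures: toy gene models, a small simulated world, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from capaudit.intervals import GeneModel, GenomeInterval
from capaudit.simulate import CohortSpec, KitSpec, SimulationConfig


@pytest.fixture
def toy_gene() -> GeneModel:
    """Two exons (100 + 50 bases) with CDS trimming 10 bases off each end."""
    return GeneModel(
        "TOY1",
        "chr1",
        "+",
        (GenomeInterval("chr1", 100, 200), GenomeInterval("chr1", 300, 350)),
        (GenomeInterval("chr1", 110, 200), GenomeInterval("chr1", 300, 340)),
    )


@pytest.fixture
def single_exon_gene() -> GeneModel:
    return GeneModel(
        "TOY2",
        "chr1",
        "-",
        (GenomeInterval("chr1", 1000, 1200),),
        (GenomeInterval("chr1", 1000, 1200),),
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    """A reduced world for fast end-to-end runs (structure, not statistics)."""
    return SimulationConfig(
        n_genes=20,
        gene_length_range=(200, 600),
        exons_per_gene_range=(1, 3),
        cohorts=[
            CohortSpec("C1", 30, "kit_biased"),
            CohortSpec("C2", 30, "kit_biased"),
            CohortSpec("C3", 30, "kit_biased"),
            CohortSpec("C4", 30, "kit_complete"),
            CohortSpec("C5", 30, "kit_complete"),
            CohortSpec("C6", 30, "kit_complete"),
        ],
        kits=[
            KitSpec("kit_biased", absent_frac=0.1, partial_frac=0.1),
            KitSpec("kit_complete"),
        ],
        seed=7,
    )


def brute_force_intersect(a, b) -> int:
    """Per-base set-membership oracle for interval intersection."""
    bases_a = {(iv.chrom, p) for iv in a for p in range(iv.start, iv.end)}
    bases_b = {(iv.chrom, p) for iv in b for p in range(iv.start, iv.end)}
    return len(bases_a & bases_b)


def random_interval_list(rng: np.random.Generator, chrom="chr1", max_len=500):
    n = int(rng.integers(0, 8))
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_len))
        end = start + int(rng.integers(1, 60))
        out.append(GenomeInterval(chrom, start, end))
    return out
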