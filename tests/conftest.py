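"""Shared fixtures: small simulated truth sets reused across test modules."""

from __future__ import annotations

import pytest

from haplotrio.hetspectrum import align_haplotypes
from haplotrio.sim import (
    Chromosome,
    IndelSpec,
    SimConfig,
    SvSpec,
    simulate_trio_genomes,
)


@pytest.fixture(scope="session")
def sv_truth():
    """Two-chromosome toy diploid with every variant class planted."""
    cfg = SimConfig(
        genome_layout=[Chromosome("chr1", 600_000), Chromosome("chr2", 400_000)],
        snv_rate=1e-3,
        indel_spec=IndelSpec(rate=5e-5),
        sv_spec=[
            SvSpec("large_indel", 4, 200, 3000),
            SvSpec("inversion", 2, 2000, 5000),
            SvSpec("translocation", 2, 1000, 3000),
            SvSpec("CNV", 2, 1000, 4000),
            SvSpec("inverted_translocation", 1, 1000, 2000),
        ],
        dnm_rate=0.0,
        seed=7,
    )
    return simulate_trio_genomes(cfg)


@pytest.fixture(scope="session")
def sv_blocks(sv_truth):
    return align_haplotypes(sv_truth.maternal, sv_truth.paternal)


@pytest.fixture(scope="session")
def snv_only_truth():
    """Gapless (SNV-only) toy diploid: child haplotypes differ base-by-base."""
    cfg = SimConfig(
        genome_layout=[Chromosome("chr1", 300_000)],
        snv_rate=1.5e-3,
        indel_spec=IndelSpec(rate=0.0),
        dnm_rate=0.0,
        seed=21,
    )
    return simulate_trio_genomes(cfg)


def sexlink_layout():
    """Autosome-dominated layout so peak normalization is unambiguous."""
    return [
        Chromosome("auto1", 10_000_000),
        Chromosome("chrX", 2_000_000, "X"),
        Chromosome("chrY", 1_000_000, "Y"),
    ]
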