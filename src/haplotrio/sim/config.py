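"""Configuration for the diploid-trio simulator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["Chromosome", "IndelSpec", "SvSpec", "SimConfig", "SV_CLASSES"]

CHROM_CLASSES = ("autosome", "X", "Y", "PAR")
SV_CLASSES = ("large_indel", "inversion", "translocation", "CNV", "inverted_translocation")


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the simulated genome layout."""

    name: str
    length: int
    chrom_class: str = "autosome"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"chromosome {self.name}: class must be one of {CHROM_CLASSES}")


@dataclass(frozen=True)
class IndelSpec:
    """Heterozygous short-indel model.

    Lengths are geometric with success probability ``p_geom`` (mean ~1/p),
    truncated at ``max_len``; insertions and deletions are equally likely.
    """

    rate: float = 0.0  # events per bp
    p_geom: float = 0.35
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("indel rate must be >= 0")
        if not 0 < self.p_geom <= 1:
            raise ValueError("p_geom must be in (0, 1]")
        if self.max_len <= 0:
            raise ValueError("max_len must be > 0")


@dataclass(frozen=True)
class SvSpec:
    """Count and length range for one planted SV class."""

    sv_class: str
    count: int
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown SV class {self.sv_class!r}; choose from {SV_CLASSES}")
        if self.count < 0:
            raise ValueError("SV count must be >= 0")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated diploid trio.

    The defaults emulate a captive-bred primate trio sequenced at 30x: a
    heterozygosity around 0.1% from SNVs alone, short indels at roughly a
    fifteenth of the SNV rate, and a per-generation mutation rate of a few
    times 1e-9 with two thirds of new mutations arising on the paternal
    haplotype.
    """

    genome_layout: Sequence[Chromosome]
    snv_rate: float = 1e-3
    indel_spec: IndelSpec = field(default_factory=IndelSpec)
    sv_spec: Sequence[SvSpec] = ()
    roh_spec: Sequence[tuple[str, int, int]] = ()  # (chrom, start, length)
    dnm_rate: float = 0.43e-8
    paternal_fraction: float = 2.0 / 3.0
    depth_mean: float = 30.0
    base_error: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genome_layout:
            raise ValueError("genome_layout must be non-empty")
        names = [c.name for c in self.genome_layout]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for rate, label in ((self.snv_rate, "snv_rate"), (self.dnm_rate, "dnm_rate")):
            if rate < 0:
                raise ValueError(f"{label} must be >= 0")
        if not 0.0 <= self.paternal_fraction <= 1.0:
            raise ValueError("paternal_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.base_error < 0.25:
            raise ValueError("base_error must be in [0, 0.25)")
        lengths = {c.name: c.length for c in self.genome_layout}
        for chrom, start, length in self.roh_spec:
            if chrom not in lengths:
                raise ValueError(f"ROH on unknown chromosome {chrom!r}")
            if length <= 0 or start < 0 or start + length > lengths[chrom]:
                raise ValueError(f"ROH ({chrom}, {start}, {length}) outside chromosome")

    @property
    def haploid_length(self) -> int:
        return sum(c.length for c in self.genome_layout)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.genome_layout:
            if c.name == name:
                return c
        raise KeyError(name)
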