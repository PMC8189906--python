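"""Heterozygosity summaries: per-class counts, window densities, overall rate.

The overall heterozygosity counts every heterozygous base — SNV bases plus
indel bases plus SV bases — over the aligned length of the maternal
haplotype, so it exceeds the SNV-only rate several-fold in a typical
diploid genome. Density tracks follow the conventional window sizes:
SNVs per 500 kb, large indels and CNVs per 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantRecord

__all__ = ["HetSummary", "summarize_heterozygosity"]

SNV_WINDOW = 500_000
SV_WINDOW = 1_000_000


@dataclass
class HetSummary:
    """Per-class counts and rates over one whole-genome comparison."""

    class_counts: dict[str, int]
    snv_rate: float  # SNVs per aligned bp
    overall_rate: float  # heterozygous bases per aligned bp
    aligned_length: int
    density_tracks: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    roh: pd.DataFrame | None = None

    @property
    def snv_percent(self) -> float:
        return 100.0 * self.snv_rate

    @property
    def overall_percent(self) -> float:
        return 100.0 * self.overall_rate


def _density(variants: list[VariantRecord], chrom_lengths: Mapping[str, int],
             window: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        edges = np.append(np.arange(0, length, window), length)
        pos = np.array([v.ref_start for v in variants if v.ref_chrom == chrom],
                       dtype=np.int64)
        counts, _ = np.histogram(pos, bins=edges)
        for i, c in enumerate(counts):
            rows.append((chrom, int(edges[i]), int(edges[i + 1]), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def summarize_heterozygosity(
    variants: Sequence[VariantRecord],
    aligned_length: int,
    chrom_lengths: Mapping[str, int] | None = None,
    roh: pd.DataFrame | None = None,
) -> HetSummary:
    """Aggregate variant records into counts, rates and density tracks."""
    if aligned_length <= 0:
        raise ValueError("aligned_length must be > 0")
    counts: dict[str, int] = {}
    snv_count = 0
    het_bases = 0
    for v in variants:
        if chrom_lengths is not None and v.ref_chrom in chrom_lengths:
            if not 0 <= v.ref_start <= chrom_lengths[v.ref_chrom]:
                raise ValueError(f"variant outside aligned coordinates: {v}")
        counts[v.var_class] = counts.get(v.var_class, 0) + 1
        het_bases += v.bases
        if v.var_class == "SNV":
            snv_count += 1
    tracks: dict[str, pd.DataFrame] = {}
    if chrom_lengths is not None:
        by_class = {"SNV": SNV_WINDOW, "large_indel": SV_WINDOW, "CNV": SV_WINDOW}
        for cls, window in by_class.items():
            sub = [v for v in variants if v.var_class == cls]
            tracks[cls] = _density(sub, chrom_lengths, window)
    return HetSummary(
        class_counts=counts,
        snv_rate=snv_count / aligned_length,
        overall_rate=het_bases / aligned_length,
        aligned_length=aligned_length,
        density_tracks=tracks,
        roh=roh,
    )
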