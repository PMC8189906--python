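"""Runs of homozygosity from the heterozygous-SNV landscape.

The genome is tiled with scan windows; windows whose SNV density falls at or
below a cutoff (default: 5% of the genome-wide mean density) are merged into
candidate runs, and only runs of at least 1 Mb are reported — long runs of
homozygosity are the signature of recent inbreeding, while short
homozygous stretches arise by chance even in outbred genomes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["detect_roh", "MIN_ROH_BP"]

MIN_ROH_BP = 1_000_000


def detect_roh(
    snv_positions: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    scan_window: int = 100_000,
    density_cutoff: float | None = None,
    min_length: int = MIN_ROH_BP,
) -> pd.DataFrame:
    """Maximal merged low-heterozygosity runs >= ``min_length`` bp.

    ``density_cutoff`` is SNVs per bp; when None it defaults to 5% of the
    genome-wide mean SNV density. Positions must be sorted per chromosome.
    """
    if scan_window <= 0:
        raise ValueError("scan_window must be > 0")
    total_snvs = sum(len(p) for p in snv_positions.values())
    total_bp = sum(chrom_lengths.values())
    if density_cutoff is None:
        density_cutoff = 0.05 * (total_snvs / total_bp if total_bp else 0.0)
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(snv_positions.get(chrom, ()), dtype=np.int64)
        if len(pos) and np.any(np.diff(pos) < 0):
            raise ValueError(f"SNV positions on {chrom} are not sorted")
        edges = np.append(np.arange(0, length, scan_window), length)
        counts, _ = np.histogram(pos, bins=edges)
        widths = np.diff(edges)
        hom = counts <= density_cutoff * widths
        start = None
        for i, h in enumerate(hom):
            if h and start is None:
                start = edges[i]
            if (not h or i == len(hom) - 1) and start is not None:
                end = edges[i] if not h else min(edges[i + 1], length)
                if end - start >= min_length:
                    rows.append((chrom, int(start), int(end)))
                start = None
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
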