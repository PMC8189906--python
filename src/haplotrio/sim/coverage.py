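"""Read-depth tracks for a female (XX) and male (XY) sample over a genome layout.

Depth is Poisson per window around the expected per-copy coverage: with a
genome-wide diploid depth D, females draw D on autosomes/PAR and X and only a
configurable mismapping noise floor on Y; males draw D on autosomes/PAR and
D/2 on X and Y. The female-to-male depth ratio is therefore ~1 on autosomes,
~2 on X and ~0 on Y, the signal the sex_linkage module classifies.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .._rng import substream
from .config import Chromosome
from .genomes import TrioGenomeTruth

__all__ = ["simulate_coverage_tracks"]


def simulate_coverage_tracks(
    layout: TrioGenomeTruth | Sequence[Chromosome],
    female_depth: float = 30.0,
    male_depth: float = 30.0,
    window_bp: int = 5000,
    seed: int = 0,
    noise_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-window depths for both samples; returns chrom/start/end/class/female/male."""
    if isinstance(layout, TrioGenomeTruth):
        layout = layout.config.genome_layout
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if female_depth <= 0 or male_depth <= 0:
        raise ValueError("depths must be > 0")
    smallest = min(c.length for c in layout)
    if window_bp > smallest:
        raise ValueError(f"window_bp={window_bp} exceeds the smallest chromosome ({smallest} bp)")

    rng = substream(seed, "coverage_tracks")
    rows = []
    for chrom in layout:
        if chrom.chrom_class in ("autosome", "PAR"):
            f_mean, m_mean = female_depth, male_depth
        elif chrom.chrom_class == "X":
            f_mean, m_mean = female_depth, male_depth / 2.0
        else:  # Y
            f_mean, m_mean = noise_floor, male_depth / 2.0
        for start in range(0, chrom.length, window_bp):
            end = min(start + window_bp, chrom.length)
            span = end - start
            f = rng.poisson(f_mean * span) / span if f_mean > 0 else 0.0
            m = rng.poisson(m_mean * span) / span if m_mean > 0 else 0.0
            rows.append((chrom.name, start, end, chrom.chrom_class, f, m))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "chrom_class",
                                       "female_depth", "male_depth"])
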