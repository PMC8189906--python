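"""Gametologue CDS pairs with planted synonymous divergence.

Each stratum plants a target dS: the X copy is a random stop-free CDS and the
Y copy carries single-nucleotide synonymous substitutions at a density whose
NG86 estimate converges to the planted dS (the substitution count is the
planted proportion p = (3/4)(1 - exp(-4 dS / 3)) times the codon-averaged
synonymous site count). X positions increase with stratum index, emulating
distance from the pseudoautosomal boundary.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .._rng import substream
from ..strata import _CODON_TABLE, STOPS, _syn_sites

__all__ = ["simulate_gametologue_pairs"]

_NONSTOP = sorted(c for c in _CODON_TABLE if c not in STOPS)
# codons that admit at least one synonymous single-nucleotide change
_SYN_ALTS: dict[str, list[str]] = {}
for _c in _NONSTOP:
    alts = []
    for _i in range(3):
        for _b in "ACGT":
            if _b == _c[_i]:
                continue
            _alt = _c[:_i] + _b + _c[_i + 1:]
            if _alt not in STOPS and _CODON_TABLE[_alt] == _CODON_TABLE[_c]:
                alts.append(_alt)
    if alts:
        _SYN_ALTS[_c] = alts


def simulate_gametologue_pairs(
    strata_spec: Sequence[tuple[int, float]],
    cds_length: int = 999,
    seed: int = 0,
    position_spacing: int = 1_000_000,
) -> pd.DataFrame:
    """One row per pair: gene, x_cds, y_cds, x_pos, stratum_true, ds_planted."""
    if cds_length % 3:
        raise ValueError("cds_length must be a multiple of 3")
    rng = substream(seed, "gametologues")
    rows = []
    pair_index = 0
    for stratum_i, (n_pairs, ds) in enumerate(strata_spec, start=1):
        if ds < 0:
            raise ValueError("planted dS must be >= 0")
        for _ in range(n_pairs):
            codons = [ _NONSTOP[int(rng.integers(len(_NONSTOP)))]
                       for _ in range(cds_length // 3) ]
            s_sites = sum(_syn_sites(c)[0] for c in codons)
            p_target = 0.75 * (1.0 - math.exp(-4.0 * ds / 3.0))
            if p_target >= 0.75:
                raise ValueError(f"planted dS={ds} saturates the Jukes-Cantor scale")
            n_subs = round(p_target * s_sites)
            mutable = [i for i, c in enumerate(codons) if c in _SYN_ALTS]
            if ds > 0 and s_sites == 0:
                raise ValueError(
                    f"planted dS={ds} unattainable: no synonymous sites in a "
                    f"{cds_length}-bp CDS draw; increase cds_length"
                )
            if n_subs > len(mutable):
                raise ValueError(
                    f"planted dS={ds} needs {n_subs} synonymous changes but only "
                    f"{len(mutable)} codons admit one; increase cds_length"
                )
            y_codons = list(codons)
            chosen = rng.choice(len(mutable), size=n_subs, replace=False) if n_subs else []
            for idx in chosen:
                c = codons[mutable[idx]]
                alts = _SYN_ALTS[c]
                y_codons[mutable[idx]] = alts[int(rng.integers(len(alts)))]
            pair_index += 1
            rows.append(dict(
                gene=f"GAM{pair_index}",
                x_cds="".join(codons),
                y_cds="".join(y_codons),
                x_pos=pair_index * position_spacing,
                stratum_true=f"S{stratum_i}",
                ds_planted=ds,
            ))
    return pd.DataFrame(rows)
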