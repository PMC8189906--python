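"""Synthetic assembly evidence chains with planted error classes.

An evidence chain records, for one haplotype at one site, the consensus base
seen at each stage of assembly: raw long reads, corrected long reads, the
pre-polish assembly, the post-polish assembly, and the short-read consensus.
Three ground-truth classes are planted:

* ``sequencing_error`` — a raw-read miscall survived into the assembly: the
  final base matches the raw consensus but conflicts with the corrected-read
  and short-read consensus.
* ``polishing_error`` — the pre-polish assembly agreed with the short reads
  and polishing moved it away.
* ``true_variant`` — all stages agree on the haplotype's base.

Consensus bases are drawn honestly from finite read depth with per-stage
miscall rates, so a small fraction of chains is ambiguous (N on ties or zero
depth), as in real pileups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._rng import substream

__all__ = ["simulate_evidence_chains"]

_BASES = np.array(list("ACGT"))


def _consensus(rng: np.random.Generator, true_idx: int, depth: int, err: float) -> str:
    if depth <= 0:
        return "N"
    probs = np.full(4, err / 3.0)
    probs[true_idx] = 1.0 - err
    counts = rng.multinomial(depth, probs)
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    return "N" if len(winners) > 1 else str(_BASES[winners[0]])


def simulate_evidence_chains(
    n_sequencing: int,
    n_polishing: int,
    n_true: int,
    depth: int = 30,
    base_error: float = 1e-3,
    seed: int = 0,
    raw_error: float = 0.10,
    corrected_error: float = 0.02,
) -> pd.DataFrame:
    """Rows: raw, corrected, pre_polish, post_polish, short, truth_class."""
    rng = substream(seed, "evidence_chains")
    rows = []
    specs = (
        [("sequencing_error",)] * n_sequencing
        + [("polishing_error",)] * n_polishing
        + [("true_variant",)] * n_true
    )
    for (cls,) in specs:
        t = int(rng.integers(4))
        e = int((t + 1 + rng.integers(3)) % 4)  # a different base
        if cls == "sequencing_error":
            raw_truth, pre, post = e, e, e
        elif cls == "polishing_error":
            raw_truth, pre, post = t, t, e
        else:
            raw_truth, pre, post = t, t, t
        rows.append(dict(
            raw=_consensus(rng, raw_truth, depth, raw_error),
            corrected=_consensus(rng, t, depth, corrected_error),
            pre_polish=str(_BASES[pre]),
            post_polish=str(_BASES[post]),
            short=_consensus(rng, t, depth, base_error),
            truth_class=cls,
        ))
    return pd.DataFrame(rows)
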