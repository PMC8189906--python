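"""Built-in exact-anchor aligner for toy diploid genomes.

Unique k-mers of the maternal (reference) assembly are located in the
paternal (query) assembly on both strands and chained into collinear blocks:
successive anchors must advance on both sides with a bounded positional gap
and a bounded diagonal shift. The diagonal band (default 50 bp) doubles as
the small/large indel boundary: indels up to the band stay inside one block
(and are recovered base-by-base later), larger ones break the chain and
surface as block junctions for SV classification.

This replaces an external whole-genome aligner only for small genomes; for
real assemblies, feed `read_alignment_blocks` the output of a standard
aligner instead.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping

import edlib
import numpy as np

from .blocks import FORWARD, REVERSE, AlignmentBlock, dedupe_blocks

__all__ = ["align_haplotypes", "AlphabetError"]

MAX_TOTAL_BP = 50_000_000


class AlphabetError(ValueError):
    pass


def _as_bytes(seq) -> bytes:
    if isinstance(seq, np.ndarray):
        seq = seq.tobytes()
    if isinstance(seq, str):
        seq = seq.upper().encode()
    if not isinstance(seq, bytes):
        raise TypeError("sequences must be str, bytes or uint8 arrays")
    if seq.translate(None, b"ACGTN"):
        raise AlphabetError("sequences may contain only A, C, G, T, N")
    return seq


_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


def align_haplotypes(
    maternal: Mapping[str, object],
    paternal: Mapping[str, object],
    anchor_len: int = 31,
    max_occ: int = 4,
    max_gap: int = 2000,
    band: int = 50,
    min_anchors: int = 3,
    min_block: int = 100,
) -> list[AlignmentBlock]:
    """Chain unique exact anchors into collinear blocks with orientation."""
    mat = {c: _as_bytes(s) for c, s in maternal.items()}
    pat = {c: _as_bytes(s) for c, s in paternal.items()}
    total = sum(map(len, mat.values())) + sum(map(len, pat.values()))
    if total > MAX_TOTAL_BP:
        raise ValueError("built-in aligner is limited to 50 Mb total; "
                         "use an external aligner and read_alignment_blocks")
    k = anchor_len

    # unique reference anchors
    index: dict[bytes, tuple[str, int] | None] = {}
    for chrom, seq in mat.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if b"N" in kmer:
                continue
            index[kmer] = None if kmer in index else (chrom, i)

    # occurrences in the query, both strands
    hits: dict[bytes, list[tuple[str, int, str]]] = defaultdict(list)
    for chrom, seq in pat.items():
        L = len(seq)
        rc = _revcomp(seq)
        for i in range(L - k + 1):
            kmer = seq[i:i + k]
            if index.get(kmer):
                hits[kmer].append((chrom, i, FORWARD))
        for i in range(L - k + 1):
            kmer = rc[i:i + k]
            if index.get(kmer):
                hits[kmer].append((chrom, L - i - k, REVERSE))

    matches = []  # (ref_chrom, ref_pos, qry_chrom, qry_pos, orient)
    for kmer, occ in hits.items():
        if len(occ) > max_occ:
            continue
        ref_chrom, ref_pos = index[kmer]
        for qry_chrom, qry_pos, orient in occ:
            matches.append((ref_chrom, ref_pos, qry_chrom, qry_pos, orient))
    matches.sort()

    # greedy chaining
    chains: list[dict] = []
    active: list[dict] = []
    for rc_, rp, qc, qp, orient in matches:
        active = [c for c in active
                  if c["ref_chrom"] == rc_ and rp - c["last_r"] <= max_gap]
        chains_alive = active
        placed = False
        for c in chains_alive:
            if c["qry_chrom"] != qc or c["orient"] != orient:
                continue
            dr = rp - c["last_r"]
            if dr < 0:
                continue
            dq = (qp - c["last_q"]) if orient == FORWARD else (c["last_q"] - qp)
            if dq < -(k - 1) or dq > max_gap:
                continue
            if abs(dq - dr) > band:
                continue
            c["last_r"], c["last_q"] = rp, qp
            c["n"] += 1
            c["min_q"] = min(c["min_q"], qp)
            c["max_q"] = max(c["max_q"], qp)
            placed = True
            break
        if not placed:
            c = dict(ref_chrom=rc_, qry_chrom=qc, orient=orient,
                     first_r=rp, last_r=rp, last_q=qp,
                     min_q=qp, max_q=qp, n=1)
            chains.append(c)
            active.append(c)

    blocks = []
    for c in chains:
        ref_start, ref_end = c["first_r"], c["last_r"] + k
        qry_start, qry_end = c["min_q"], c["max_q"] + k
        if c["n"] < min_anchors or ref_end - ref_start < min_block:
            continue
        ref_sub = mat[c["ref_chrom"]][ref_start:ref_end]
        qry_sub = pat[c["qry_chrom"]][qry_start:qry_end]
        if c["orient"] == REVERSE:
            qry_sub = _revcomp(qry_sub)
        dist = edlib.align(qry_sub, ref_sub, task="distance", mode="NW")["editDistance"]
        ident = 100.0 * (1.0 - dist / max(len(ref_sub), len(qry_sub)))
        blocks.append(AlignmentBlock(c["ref_chrom"], ref_start, ref_end,
                                     c["qry_chrom"], qry_start, qry_end,
                                     c["orient"], max(ident, 0.0)))
    return dedupe_blocks(blocks)
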