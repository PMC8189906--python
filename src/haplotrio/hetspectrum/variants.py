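"""Base-level variant extraction inside collinear blocks.

Each block's two substrings are aligned end-to-end with edlib; variant
clusters are then locally realigned with affine gap penalties so that one
heterozygous indel is reported as one contiguous gap (unit-cost alignments
may split a gap across co-optimal paths in repetitive micro-context).
Mismatch columns become SNVs and gaps up to 50 bp become short indels;
longer gaps are left to the block-junction SV classifier — heterozygous
indels are "short" up to 50 bp, anything larger is a structural variant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping

import edlib
from Bio import Align

from .blocks import REVERSE, AlignmentBlock

__all__ = ["VariantRecord", "extract_small_variants", "left_normalize",
           "SMALL_INDEL_MAX"]

SMALL_INDEL_MAX = 50
_CIGAR_RE = re.compile(r"(\d+)([=XID])")
_CLUSTER_WINDOW = 30  # bp of reference separation that merges events into a cluster
_PAD = 12

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass(frozen=True)
class VariantRecord:
    """One heterozygous difference between the two haplotypes."""

    var_class: str  # SNV, small_indel, large_indel, inversion, translocation,
    #                 CNV, inverted_translocation
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    length: int
    ref_allele: str = ""
    alt_allele: str = ""
    kind: str = ""  # insertion/deletion for indels, duplication for CNV, ...
    support: str = "unresolved"
    copy_count: int = 0

    @property
    def bases(self) -> int:
        """Heterozygous bases this variant contributes (SNV=1, others=length)."""
        return self.length


def _seq_bytes(seq) -> bytes:
    if isinstance(seq, str):
        return seq.upper().encode()
    if hasattr(seq, "tobytes"):
        return seq.tobytes()
    return bytes(seq)


def _affine_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _affine_aligner()


def _events_from_cigar(cigar: str) -> list[tuple[str, int, int, int]]:
    """(op, ref_off, qry_off, length) for X/I/D runs of an edlib NW cigar."""
    events = []
    ri = qi = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op == "=":
            ri, qi = ri + n, qi + n
        elif op == "X":
            events.append(("X", ri, qi, n))
            ri, qi = ri + n, qi + n
        elif op == "I":
            events.append(("I", ri, qi, n))
            qi += n
        else:
            events.append(("D", ri, qi, n))
            ri += n
    return events


def _events_from_affine(ref_seg: bytes, qry_seg: bytes) -> list[tuple[str, int, int, int]]:
    aln = _ALIGNER.align(ref_seg.decode(), qry_seg.decode())[0]
    ref_blocks, qry_blocks = aln.aligned
    events: list[tuple[str, int, int, int]] = []
    prev_r = prev_q = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
        if rs > prev_r:
            events.append(("D", prev_r, prev_q, rs - prev_r))
        if qs > prev_q:
            events.append(("I", rs, prev_q, qs - prev_q))
        run = None
        for off in range(re_ - rs):
            if ref_seg[rs + off] != qry_seg[qs + off]:
                if run is not None and rs + off == run[1] + run[3]:
                    run = ("X", run[1], run[2], run[3] + 1)
                    events[-1] = run
                else:
                    run = ("X", rs + off, qs + off, 1)
                    events.append(run)
            else:
                run = None
        prev_r, prev_q = re_, qe
    if len(ref_seg) > prev_r:
        events.append(("D", prev_r, prev_q, len(ref_seg) - prev_r))
    if len(qry_seg) > prev_q:
        events.append(("I", len(ref_seg), prev_q, len(qry_seg) - prev_q))
    return sorted(events, key=lambda e: (e[1], e[2]))


def _cluster_and_realign(events, ref_sub: bytes, qry_sub: bytes):
    """Realign clusters of nearby events with affine gaps; pass lone SNVs through."""
    out = []
    i = 0
    n = len(events)
    while i < n:
        j = i
        while (j + 1 < n
               and events[j + 1][1] - (events[j][1] + (events[j][3] if events[j][0] != "I" else 0))
               <= _CLUSTER_WINDOW):
            j += 1
        cluster = events[i:j + 1]
        has_indel = any(e[0] in "ID" for e in cluster)
        if len(cluster) == 1 and not has_indel:
            out.extend(cluster)
        elif not has_indel:
            out.extend(cluster)  # SNV runs need no gap placement
        else:
            r0 = max(cluster[0][1] - _PAD, 0)
            last = cluster[-1]
            r1 = min(last[1] + (last[3] if last[0] != "I" else 0) + _PAD, len(ref_sub))
            q0 = max(cluster[0][2] - _PAD, 0)
            q1 = min(last[2] + (last[3] if last[0] != "D" else 0) + _PAD, len(qry_sub))
            for op, ro, qo, ln in _events_from_affine(ref_sub[r0:r1], qry_sub[q0:q1]):
                out.append((op, r0 + ro, q0 + qo, ln))
        i = j + 1
    return out


def left_normalize(rec: VariantRecord, ref_seqs: Mapping[str, object],
                   qry_seqs: Mapping[str, object]) -> VariantRecord:
    """Shift an indel to its leftmost equivalent placement (VCF convention).

    SNVs and non-indel classes are returned unchanged. Normalization makes
    indel calls comparable across alignments that place a gap at different
    but equivalent positions of a repeat.
    """
    if rec.var_class not in ("small_indel", "large_indel") or rec.length == 0:
        return rec
    ref = _seq_bytes(ref_seqs[rec.ref_chrom])
    if rec.kind == "deletion":
        s, e = rec.ref_start, rec.ref_end
        while s > 0 and ref[s - 1] == ref[e - 1]:
            s -= 1
            e -= 1
        shift = rec.ref_start - s
        return replace(rec, ref_start=s, ref_end=e,
                       ref_allele=ref[s:e].decode(),
                       qry_start=rec.qry_start - shift, qry_end=rec.qry_end - shift)
    if rec.kind == "insertion":
        allele = bytearray(rec.alt_allele.encode())
        s = rec.ref_start
        shift = 0
        while s > 0 and ref[s - 1] == allele[-1]:
            allele = bytearray([ref[s - 1]]) + allele[:-1]
            s -= 1
            shift += 1
        return replace(rec, ref_start=s, ref_end=s, alt_allele=allele.decode(),
                       qry_start=rec.qry_start - shift, qry_end=rec.qry_end - shift)
    return rec


def extract_small_variants(
    blocks: list[AlignmentBlock],
    maternal: Mapping[str, object],
    paternal: Mapping[str, object],
    max_small: int = SMALL_INDEL_MAX,
    normalize: bool = True,
) -> list[VariantRecord]:
    """SNVs and indels <= ``max_small`` bp from within-block alignments.

    Blocks must be non-overlapping per locus pair (see ``dedupe_blocks``);
    gaps longer than ``max_small`` are skipped here and surface as SV
    junctions instead. Indels are left-normalized by default.
    """
    mat = {c: _seq_bytes(s) for c, s in maternal.items()}
    pat = {c: _seq_bytes(s) for c, s in paternal.items()}
    out: list[VariantRecord] = []
    for blk in blocks:
        ref_seq = mat[blk.ref_chrom]
        qry_seq = pat[blk.qry_chrom]
        if blk.ref_end > len(ref_seq) or blk.qry_end > len(qry_seq):
            raise ValueError(f"block exceeds sequence bounds: {blk}")
        ref_sub = ref_seq[blk.ref_start:blk.ref_end]
        qry_sub = qry_seq[blk.qry_start:blk.qry_end]
        reverse = blk.orientation == REVERSE
        if reverse:
            qry_sub = qry_sub.translate(_RC)[::-1]
        cigar = edlib.align(qry_sub, ref_sub, task="path", mode="NW")["cigar"]
        events = _cluster_and_realign(_events_from_cigar(cigar), ref_sub, qry_sub)

        def qry_genome(qi: int, span: int) -> tuple[int, int]:
            if reverse:
                return blk.qry_end - qi - span, blk.qry_end - qi
            return blk.qry_start + qi, blk.qry_start + qi + span

        for op, ri, qi, ln in events:
            if op == "X":
                for j in range(ln):
                    qs, qe = qry_genome(qi + j, 1)
                    out.append(VariantRecord(
                        "SNV", blk.ref_chrom, blk.ref_start + ri + j,
                        blk.ref_start + ri + j + 1, blk.qry_chrom, qs, qe, 1,
                        ref_allele=chr(ref_sub[ri + j]),
                        alt_allele=chr(qry_sub[qi + j]), kind="snv"))
            elif op == "I" and ln <= max_small:
                qs, qe = qry_genome(qi, ln)
                out.append(VariantRecord(
                    "small_indel", blk.ref_chrom, blk.ref_start + ri,
                    blk.ref_start + ri, blk.qry_chrom, qs, qe, ln,
                    alt_allele=qry_sub[qi:qi + ln].decode(), kind="insertion"))
            elif op == "D" and ln <= max_small:
                qs, qe = qry_genome(qi, 0)
                out.append(VariantRecord(
                    "small_indel", blk.ref_chrom, blk.ref_start + ri,
                    blk.ref_start + ri + ln, blk.qry_chrom, qs, qe, ln,
                    ref_allele=ref_sub[ri:ri + ln].decode(), kind="deletion"))
    if normalize:
        out = [left_normalize(v, mat, pat) for v in out]
    return out
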