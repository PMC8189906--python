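"""Structural-variant classification from block junctions, and read validation.

Classification works on the sorted block list of one whole-genome alignment:

* CNV — one interval of one haplotype matched by two or more disjoint loci of
  the other (copy count = number of matched loci);
* translocation — a block relocated to another chromosome or to a
  non-collinear position (inverted_translocation when also reverse);
* inversion — a reverse-orientation block whose position is collinear with
  its neighbours;
* large indel — a net length difference above 50 bp between adjacent
  collinear blocks.

Each junction receives exactly one class, by the precedence
CNV > inverted_translocation > inversion > translocation > large_indel:
junction gaps already explained by a relocated or duplicated block are
suppressed from indel calling.
"""

from __future__ import annotations

from bisect import insort
from typing import Sequence

import edlib

from .blocks import FORWARD, REVERSE, AlignmentBlock
from .variants import SMALL_INDEL_MAX, VariantRecord, _seq_bytes, _RC

__all__ = ["classify_svs", "validate_sv_with_reads"]


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _weighted_lis(blocks: list[AlignmentBlock]) -> set[int]:
    """Indices of the max-weight subset collinear in both ref and qry order."""
    n = len(blocks)
    best = [b.ref_len for b in blocks]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if (blocks[j].qry_end <= blocks[i].qry_start + SMALL_INDEL_MAX
                    and best[j] + blocks[i].ref_len > best[i]):
                best[i] = best[j] + blocks[i].ref_len
                prev[i] = j
    if not n:
        return set()
    i = max(range(n), key=lambda x: best[x])
    chain = set()
    while i >= 0:
        chain.add(i)
        i = prev[i]
    return chain


def classify_svs(
    blocks: Sequence[AlignmentBlock],
    min_sv: int = SMALL_INDEL_MAX,
    colinear_tol: int = 10_000,
    cnv_min_overlap: int = SMALL_INDEL_MAX,
) -> list[VariantRecord]:
    """Classify block junctions into SV records (> ``min_sv`` bp classes)."""
    blocks = list(blocks)
    for a, b in zip(blocks, blocks[1:]):
        if (a.ref_chrom, a.ref_start) > (b.ref_chrom, b.ref_start):
            raise ValueError("blocks must be sorted by (ref_chrom, ref_start)")
    records: list[VariantRecord] = []
    consumed: set[int] = set()  # block indices explained by a relocation/duplication
    suppress_ref: list[tuple[str, int, int]] = []  # intervals explained away
    suppress_qry: list[tuple[str, int, int]] = []

    # --- CNV: one interval matched by two inconsistent loci of the other side.
    # Two blocks sharing sequence on one haplotype represent an extra copy
    # when their mappings disagree: different chromosome, different diagonal
    # (forward pairs) or plainly disjoint intervals on the other side.
    def diag(b: AlignmentBlock) -> int:
        return b.qry_start - b.ref_start

    def same_locus(a: AlignmentBlock, b: AlignmentBlock) -> bool:
        if a.qry_chrom != b.qry_chrom or a.orientation != b.orientation:
            return False
        if a.orientation == FORWARD:
            return abs(diag(a) - diag(b)) <= 2 * SMALL_INDEL_MAX
        return _overlap(a.qry_start, a.qry_end, b.qry_start, b.qry_end) > 0

    n = len(blocks)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = blocks[i], blocks[j]
            if {i, j} & consumed:
                continue
            ref_shared = (a.ref_chrom == b.ref_chrom
                          and _overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end)
                          >= cnv_min_overlap)
            if ref_shared and not same_locus(a, b):
                # the extra copy is the less collinear of the two
                extra = (i if (a.qry_chrom != a.ref_chrom
                               or abs(diag(a)) > abs(diag(b))) else j)
                eb = blocks[extra]
                lo = max(a.ref_start, b.ref_start)
                hi = min(a.ref_end, b.ref_end)
                records.append(VariantRecord(
                    "CNV", eb.ref_chrom, lo, hi, eb.qry_chrom, eb.qry_start,
                    eb.qry_end, hi - lo, kind="duplication", copy_count=2))
                consumed.add(extra)
                suppress_qry.append((eb.qry_chrom, eb.qry_start, eb.qry_end))
                continue
            qry_shared = (a.qry_chrom == b.qry_chrom
                          and _overlap(a.qry_start, a.qry_end, b.qry_start, b.qry_end)
                          >= cnv_min_overlap)
            if qry_shared and not same_locus(a, b) and a.ref_chrom == b.ref_chrom \
                    and _overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end) == 0:
                extra = (i if (a.qry_chrom != a.ref_chrom
                               or abs(diag(a)) > abs(diag(b))) else j)
                eb = blocks[extra]
                lo = max(a.qry_start, b.qry_start)
                hi = min(a.qry_end, b.qry_end)
                records.append(VariantRecord(
                    "CNV", eb.ref_chrom, eb.ref_start, eb.ref_end, eb.qry_chrom,
                    lo, hi, hi - lo, kind="duplication", copy_count=2))
                consumed.add(extra)
                suppress_ref.append((eb.ref_chrom, eb.ref_start, eb.ref_end))

    # --- relocations and inversions, per reference chromosome -----------------
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(blocks):
        if i not in consumed:
            by_chrom.setdefault(b.ref_chrom, []).append(i)

    chain_blocks: dict[str, list[int]] = {}
    for chrom, idxs in by_chrom.items():
        lens: dict[str, int] = {}
        for i in idxs:
            lens[blocks[i].qry_chrom] = lens.get(blocks[i].qry_chrom, 0) + blocks[i].ref_len
        main_qry = max(lens, key=lens.get)
        for i in idxs:
            b = blocks[i]
            if b.qry_chrom != main_qry:
                cls = ("inverted_translocation" if b.orientation == REVERSE
                       else "translocation")
                records.append(VariantRecord(
                    cls, b.ref_chrom, b.ref_start, b.ref_end, b.qry_chrom,
                    b.qry_start, b.qry_end, b.ref_len, kind="translocation"))
                consumed.add(i)
                suppress_ref.append((b.ref_chrom, b.ref_start, b.ref_end))
                suppress_qry.append((b.qry_chrom, b.qry_start, b.qry_end))
        fwd = [i for i in idxs if i not in consumed
               and blocks[i].orientation == FORWARD]
        in_chain = {fwd[x] for x in _weighted_lis([blocks[i] for i in fwd])}
        for i in fwd:
            if i not in in_chain:
                b = blocks[i]
                records.append(VariantRecord(
                    "translocation", b.ref_chrom, b.ref_start, b.ref_end,
                    b.qry_chrom, b.qry_start, b.qry_end, b.ref_len,
                    kind="translocation"))
                consumed.add(i)
                suppress_ref.append((b.ref_chrom, b.ref_start, b.ref_end))
                suppress_qry.append((b.qry_chrom, b.qry_start, b.qry_end))
        chain = sorted(in_chain, key=lambda i: blocks[i].ref_start)
        rev = [i for i in idxs if i not in consumed and blocks[i].orientation == REVERSE]
        for i in rev:
            b = blocks[i]
            prevs = [j for j in chain if blocks[j].ref_start < b.ref_start]
            nexts = [j for j in chain if blocks[j].ref_start > b.ref_start]
            lo = blocks[prevs[-1]].qry_end if prevs else b.qry_start - colinear_tol
            hi = blocks[nexts[0]].qry_start if nexts else b.qry_end + colinear_tol
            colinear = (lo - colinear_tol <= b.qry_start
                        and b.qry_end <= hi + colinear_tol)
            if colinear:
                records.append(VariantRecord(
                    "inversion", b.ref_chrom, b.ref_start, b.ref_end, b.qry_chrom,
                    b.qry_start, b.qry_end, b.ref_len, kind="inversion"))
                insort(chain, i, key=lambda j: blocks[j].ref_start)
            else:
                records.append(VariantRecord(
                    "inverted_translocation", b.ref_chrom, b.ref_start, b.ref_end,
                    b.qry_chrom, b.qry_start, b.qry_end, b.ref_len,
                    kind="translocation"))
                consumed.add(i)
                suppress_ref.append((b.ref_chrom, b.ref_start, b.ref_end))
                suppress_qry.append((b.qry_chrom, b.qry_start, b.qry_end))
        chain_blocks[chrom] = chain

    # --- large indels at junctions of the collinear chain ---------------------
    def explained(intervals, chrom, lo, hi) -> bool:
        span = hi - lo
        if span <= 0:
            return False
        cov = sum(_overlap(lo, hi, s, e) for c, s, e in intervals if c == chrom)
        return cov >= 0.5 * span

    for chrom, chain in chain_blocks.items():
        for i, j in zip(chain, chain[1:]):
            a, b = blocks[i], blocks[j]
            ref_gap = b.ref_start - a.ref_end
            qry_gap = b.qry_start - a.qry_end
            net = ref_gap - qry_gap
            if abs(net) <= min_sv:
                continue
            if net > 0:  # extra maternal bases: a deletion in the paternal haplotype
                if explained(suppress_ref, chrom, a.ref_end, b.ref_start):
                    continue
                records.append(VariantRecord(
                    "large_indel", chrom, a.ref_end, b.ref_start, a.qry_chrom,
                    a.qry_end, b.qry_start, net, kind="deletion"))
            else:
                if explained(suppress_qry, a.qry_chrom, a.qry_end, b.qry_start):
                    continue
                records.append(VariantRecord(
                    "large_indel", chrom, a.ref_end, b.ref_start, a.qry_chrom,
                    a.qry_end, b.qry_start, -net, kind="insertion"))
    return records


def validate_sv_with_reads(
    sv: VariantRecord,
    maternal=None,
    paternal=None,
    long_reads: Sequence[str] | None = None,
    linked_read_count: int | None = None,
    min_identity: float = 96.0,
    min_aligned: int = 550,
    min_similarity: float = 90.0,
    min_linked_reads: int = 5,
    flank: int = 300,
) -> str:
    """Two-step SV validation; returns one of
    read_supported / linked_read_supported / rejected / unresolved.

    Step 1 clips ``flank``-bp flanks around the break point on both
    haplotypes and requires a local long read matching the junction at
    > ``min_identity`` % over > ``min_aligned`` bp, with the two haplotypes'
    junction regions themselves > ``min_similarity`` % similar. If step 1
    fails, step 2 requires at least ``min_linked_reads`` linked-read
    barcodes within the 5-kb flanking region.
    """
    def junction(seq_map, chrom, pos):
        """Contiguous ``2*flank`` bp spanning one break point."""
        seq = _seq_bytes(seq_map[chrom])
        if pos - flank < 0 or pos + flank > len(seq):
            return None  # break point too close to a contig end
        return seq[pos - flank:pos + flank]

    step1 = None
    if long_reads and maternal is not None and paternal is not None:
        junctions = [junction(maternal, sv.ref_chrom, sv.ref_start),
                     junction(maternal, sv.ref_chrom, sv.ref_end),
                     junction(paternal, sv.qry_chrom, sv.qry_start),
                     junction(paternal, sv.qry_chrom, sv.qry_end)]
        if any(j is None for j in junctions):
            return "unresolved"  # flank error
        # cross-haplotype similarity of the SV region itself (orientation-aware;
        # a one-sided region, e.g. a pure deletion, has nothing to compare)
        mseq = _seq_bytes(maternal[sv.ref_chrom])
        pseq = _seq_bytes(paternal[sv.qry_chrom])
        reg_m = mseq[sv.ref_start:sv.ref_end]
        reg_p = pseq[sv.qry_start:sv.qry_end]
        if min(len(reg_m), len(reg_p)) == 0:
            similarity = 100.0
        else:
            sims = []
            for candidate in (reg_p, reg_p.translate(_RC)[::-1]):
                dist = edlib.align(reg_m, candidate, task="distance",
                                   mode="NW")["editDistance"]
                sims.append(100.0 * (1 - dist / max(len(reg_m), len(candidate))))
            similarity = max(sims)
        best, best_len = 0.0, 0
        for read in long_reads:
            rb = _seq_bytes(read)
            for target in (rb, rb.translate(_RC)[::-1]):
                for jseq in junctions:
                    hit = edlib.align(jseq, target, task="distance", mode="HW")
                    if hit["editDistance"] < 0:
                        continue
                    ident = 100.0 * (1 - hit["editDistance"] / len(jseq))
                    if ident > best:
                        best, best_len = ident, len(jseq)
        step1 = (best > min_identity and best_len > min_aligned
                 and similarity > min_similarity)
        if step1:
            return "read_supported"
    if linked_read_count is not None:
        if linked_read_count >= min_linked_reads:
            return "linked_read_supported"
        if step1 is False:
            return "rejected"
    return "unresolved"
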