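"""Collinear alignment blocks between the two haplotype assemblies.

Blocks use 0-based half-open coordinates on both sides with start < end; a
``reverse`` orientation flag marks minus-strand matches. Readers accept the
two standard whole-genome-alignment exports: `show-coords -TH` tables
(1-based inclusive, reverse matches encoded as query start > end) and PAF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

__all__ = ["AlignmentBlock", "read_alignment_blocks", "dedupe_blocks"]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class AlignmentBlock:
    """One collinear match: maternal (ref) interval vs paternal (qry) interval."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orientation: str = FORWARD
    identity: float = 100.0

    def __post_init__(self) -> None:
        if not (self.ref_start < self.ref_end and self.qry_start < self.qry_end):
            raise ValueError(f"block intervals must satisfy start < end: {self}")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be '{FORWARD}' or '{REVERSE}'")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start


class BlockParseError(ValueError):
    pass


def _parse_coords_row(fields: list[str], lineno: int) -> AlignmentBlock:
    # show-coords -TH: S1 E1 S2 E2 LEN1 LEN2 %IDY ... ref_tag qry_tag
    if len(fields) < 9:
        raise BlockParseError(f"line {lineno}: expected >= 9 tab-separated fields")
    try:
        s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
        idy = float(fields[6])
    except ValueError as exc:
        raise BlockParseError(f"line {lineno}: {exc}") from exc
    ref_chrom, qry_chrom = fields[-2], fields[-1]
    if e1 < s1:
        raise BlockParseError(f"line {lineno}: reference end < start in coords dialect")
    if s2 <= e2:
        qs, qe, orient = s2 - 1, e2, FORWARD
    else:  # reverse matches are reported query-descending
        qs, qe, orient = e2 - 1, s2, REVERSE
    return AlignmentBlock(ref_chrom, s1 - 1, e1, qry_chrom, qs, qe, orient, idy)


def _parse_paf_row(fields: list[str], lineno: int) -> AlignmentBlock:
    if len(fields) < 12:
        raise BlockParseError(f"line {lineno}: expected >= 12 PAF fields")
    try:
        qname, _qlen, qstart, qend = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
        strand = fields[4]
        tname, _tlen, tstart, tend = fields[5], int(fields[6]), int(fields[7]), int(fields[8])
        nmatch, alen = int(fields[9]), int(fields[10])
    except ValueError as exc:
        raise BlockParseError(f"line {lineno}: {exc}") from exc
    if strand not in "+-":
        raise BlockParseError(f"line {lineno}: bad strand {strand!r}")
    identity = 100.0 * nmatch / alen if alen else 0.0
    return AlignmentBlock(tname, tstart, tend, qname, qstart, qend,
                          FORWARD if strand == "+" else REVERSE, identity)


def read_alignment_blocks(path: str | Path, dialect: str) -> list[AlignmentBlock]:
    """Read blocks from a `show-coords -TH` table or a PAF file.

    The target/reference side is taken as the maternal assembly. An empty
    file yields an empty list; a malformed row raises with its line number.
    """
    if dialect not in ("coords", "paf"):
        raise ValueError("dialect must be 'coords' or 'paf'")
    parse = _parse_coords_row if dialect == "coords" else _parse_paf_row
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            blocks.append(parse(line.split("\t"), lineno))
    return blocks


def dedupe_blocks(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Resolve duplicate representations of the same locus pair.

    Only blocks overlapping on BOTH haplotypes compete (repeat-induced
    double representation); overlap on one side alone is genuine signal (a
    duplication) and both blocks are kept. The higher-identity block keeps
    the contested bases; ties go to the longer block, then to the
    lexicographically smaller query chromosome. The losing block is trimmed
    on the reference side (and dropped when swallowed), its query side
    shifted by the trimmed span.
    """
    order = sorted(blocks, key=lambda b: (-b.identity, -b.ref_len, b.qry_chrom))
    kept: list[AlignmentBlock] = []
    for blk in order:
        cur = blk
        dead = False
        for other in kept:
            if (other.ref_chrom != cur.ref_chrom or other.qry_chrom != cur.qry_chrom
                    or other.orientation != cur.orientation):
                continue
            if min(cur.qry_end, other.qry_end) <= max(cur.qry_start, other.qry_start):
                continue
            lo = max(cur.ref_start, other.ref_start)
            hi = min(cur.ref_end, other.ref_end)
            if lo >= hi:
                continue
            if other.ref_start <= cur.ref_start and cur.ref_end <= other.ref_end:
                dead = True
                break
            if cur.ref_start < other.ref_start:  # trim our right edge
                cut = cur.ref_end - other.ref_start
                new_ref_end = other.ref_start
                if cur.orientation == FORWARD:
                    cur = replace(cur, ref_end=new_ref_end,
                                  qry_end=max(cur.qry_start + 1, cur.qry_end - cut))
                else:
                    cur = replace(cur, ref_end=new_ref_end,
                                  qry_start=min(cur.qry_end - 1, cur.qry_start + cut))
            else:  # trim our left edge
                cut = other.ref_end - cur.ref_start
                if cur.orientation == FORWARD:
                    cur = replace(cur, ref_start=other.ref_end,
                                  qry_start=min(cur.qry_end - 1, cur.qry_start + cut))
                else:
                    cur = replace(cur, ref_start=other.ref_end,
                                  qry_end=max(cur.qry_start + 1, cur.qry_end - cut))
            if cur.ref_start >= cur.ref_end:
                dead = True
                break
        if not dead:
            kept.append(cur)
    return sorted(kept, key=lambda b: (b.ref_chrom, b.ref_start))
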