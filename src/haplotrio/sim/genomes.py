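"""Diploid-trio genome simulator with machine-readable truth tables.

The simulator builds an ancestral genome, treats it as the transmitted
maternal haplotype, and derives the transmitted paternal haplotype by
planting heterozygous SNVs, short indels and structural variants outside the
configured runs of homozygosity (ROH). De novo mutations (DNMs) are then
planted independently on the two transmitted haplotypes to form the child's
maternal- and paternal-inherited sequences, with a configurable fraction of
DNMs of paternal origin.

Every planted event is recorded with coordinates on both haplotypes, so any
downstream caller can be scored against exact truth.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import substream
from .config import SimConfig

__all__ = ["TrioGenomeTruth", "PlacementError", "simulate_trio_genomes"]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MARGIN = 200  # bp kept clear around every planted event footprint


class PlacementError(RuntimeError):
    """Raised when a variant cannot be placed without overlap after bounded resampling."""


@dataclass
class TrioGenomeTruth:
    """Truth set of one simulated trio.

    Sequences are dicts of chromosome name -> uint8 ASCII arrays.
    ``maternal``/``paternal`` are the transmitted parental haplotypes;
    ``child_maternal``/``child_paternal`` additionally carry the planted DNMs.
    """

    config: SimConfig
    maternal: dict[str, np.ndarray]
    paternal: dict[str, np.ndarray]
    child_maternal: dict[str, np.ndarray]
    child_paternal: dict[str, np.ndarray]
    variants: pd.DataFrame  # planted inherited heterozygous differences
    dnms: pd.DataFrame  # planted de novo mutations
    roh: pd.DataFrame  # planted homozygous runs
    edits: dict[str, list] = field(default_factory=dict, repr=False)

    def haplotype_fastas(self) -> dict[str, dict[str, str]]:
        """Sequences as plain strings, keyed by haplotype then chromosome."""
        return {
            name: {c: seqs[c].tobytes().decode() for c in seqs}
            for name, seqs in (
                ("maternal", self.maternal),
                ("paternal", self.paternal),
                ("child_maternal", self.child_maternal),
                ("child_paternal", self.child_paternal),
            )
        }


class _Registry:
    """Sorted non-overlapping occupied intervals on one chromosome."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def collides(self, start: int, end: int) -> bool:
        i = bisect_left(self.starts, end)
        if i > 0 and self.ends[i - 1] > start:
            return True
        return i < len(self.starts) and self.starts[i] < end

    def add(self, start: int, end: int) -> None:
        i = bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)

    def mask_free(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of positions not inside any occupied interval."""
        if not self.starts:
            return np.ones(len(positions), dtype=bool)
        idx = np.searchsorted(np.asarray(self.starts), positions, side="right")
        ends = np.asarray(self.ends)
        inside = (idx > 0) & (positions < ends[np.maximum(idx - 1, 0)])
        return ~inside


def _revcomp(seq: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    comp[ord("A")] = ord("T")
    comp[ord("T")] = ord("A")
    comp[ord("C")] = ord("G")
    comp[ord("G")] = ord("C")
    comp[ord("N")] = ord("N")
    return comp[seq[::-1]]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _other_base(rng: np.random.Generator, base: np.ndarray) -> np.ndarray:
    """Uniformly draw a different base for each entry of ``base``."""
    idx = np.searchsorted(BASES, base)  # BASES is sorted (ACGT)
    shift = rng.integers(1, 4, size=len(base))
    return BASES[(idx + shift) % 4]


def _place(
    rng: np.random.Generator,
    registry: _Registry,
    chrom_len: int,
    length: int,
    attempts: int = 100,
) -> int:
    """Draw a start for an event of ``length`` bp avoiding occupied intervals."""
    for _ in range(attempts):
        if chrom_len - length - 2 * _MARGIN <= 0:
            break
        start = int(rng.integers(_MARGIN, chrom_len - length - _MARGIN))
        if not registry.collides(start - _MARGIN, start + length + _MARGIN):
            registry.add(start - _MARGIN, start + length + _MARGIN)
            return start
    raise PlacementError(
        f"could not place a {length}-bp event after {attempts} attempts; "
        "reduce rates/counts or enlarge the genome"
    )


def simulate_trio_genomes(config: SimConfig) -> TrioGenomeTruth:
    """Simulate parental haplotypes, transmit them to a child, and plant DNMs."""
    rng = substream(config.seed, "trio_genomes")
    lengths = {c.name: c.length for c in config.genome_layout}

    maternal = {name: _random_sequence(rng, L) for name, L in lengths.items()}

    registries = {name: _Registry() for name in lengths}
    roh_rows = []
    for chrom, start, length in config.roh_spec:
        registries[chrom].add(start, start + length)
        roh_rows.append((chrom, start, start + length))
    roh = pd.DataFrame(roh_rows, columns=["chrom", "start", "end"])

    # --- structural variants (few, individually placed) --------------------
    edits: dict[str, list] = {name: [] for name in lengths}  # local ops per chrom
    var_rows: list[dict] = []
    chrom_names = list(lengths)
    for spec in config.sv_spec:
        for i in range(spec.count):
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            if spec.sv_class == "large_indel":
                if i % 2 == 0:  # deletion from the paternal haplotype
                    start = _place(rng, registries[chrom], lengths[chrom], length)
                    edits[chrom].append((start, "del", length, None))
                    var_rows.append(dict(var_class="large_indel", ref_chrom=chrom,
                                         ref_start=start, ref_end=start + length,
                                         qry_chrom=chrom, length=length, kind="deletion"))
                else:  # insertion of novel sequence into the paternal haplotype
                    start = _place(rng, registries[chrom], lengths[chrom], 1)
                    payload = _random_sequence(rng, length)
                    edits[chrom].append((start, "ins", length, payload))
                    var_rows.append(dict(var_class="large_indel", ref_chrom=chrom,
                                         ref_start=start, ref_end=start,
                                         qry_chrom=chrom, length=length, kind="insertion"))
            elif spec.sv_class == "inversion":
                start = _place(rng, registries[chrom], lengths[chrom], length)
                edits[chrom].append((start, "inv", length, None))
                var_rows.append(dict(var_class="inversion", ref_chrom=chrom,
                                     ref_start=start, ref_end=start + length,
                                     qry_chrom=chrom, length=length, kind="inversion"))
            elif spec.sv_class in ("translocation", "inverted_translocation"):
                if len(chrom_names) < 2:
                    raise PlacementError("translocations need at least two chromosomes")
                src = chrom
                dst = chrom_names[(chrom_names.index(src) + 1) % len(chrom_names)]
                start = _place(rng, registries[src], lengths[src], length)
                tpos = _place(rng, registries[dst], lengths[dst], 1)
                payload = maternal[src][start:start + length].copy()
                inverted = spec.sv_class == "inverted_translocation"
                if inverted:
                    payload = _revcomp(payload)
                edits[src].append((start, "del", length, None))
                edits[dst].append((tpos, "ins", length, payload))
                var_rows.append(dict(var_class=spec.sv_class, ref_chrom=src,
                                     ref_start=start, ref_end=start + length,
                                     qry_chrom=dst, length=length, kind="translocation",
                                     target_pos=tpos))
            elif spec.sv_class == "CNV":
                start = _place(rng, registries[chrom], lengths[chrom], length)
                tpos = _place(rng, registries[chrom], lengths[chrom], 1)
                payload = maternal[chrom][start:start + length].copy()
                edits[chrom].append((tpos, "ins", length, payload))
                var_rows.append(dict(var_class="CNV", ref_chrom=chrom,
                                     ref_start=start, ref_end=start + length,
                                     qry_chrom=chrom, length=length, kind="duplication",
                                     target_pos=tpos, copy_count=2))

    # --- short indels -------------------------------------------------------
    for chrom, L in lengths.items():
        n = rng.poisson(config.indel_spec.rate * L)
        for i in range(int(n)):
            length = min(int(rng.geometric(config.indel_spec.p_geom)), config.indel_spec.max_len)
            if i % 2 == 0:
                start = _place(rng, registries[chrom], L, length)
                edits[chrom].append((start, "del", length, None))
                var_rows.append(dict(var_class="small_indel", ref_chrom=chrom,
                                     ref_start=start, ref_end=start + length,
                                     qry_chrom=chrom, length=length, kind="deletion"))
            else:
                start = _place(rng, registries[chrom], L, 1)
                payload = _random_sequence(rng, length)
                edits[chrom].append((start, "ins", length, payload))
                var_rows.append(dict(var_class="small_indel", ref_chrom=chrom,
                                     ref_start=start, ref_end=start,
                                     qry_chrom=chrom, length=length, kind="insertion"))

    # --- SNVs (bulk placement) ---------------------------------------------
    for chrom, L in lengths.items():
        n = int(rng.poisson(config.snv_rate * L))
        pool = np.empty(0, dtype=np.int64)
        for _ in range(100):
            if len(pool) >= n:
                break
            cand = rng.integers(0, L, size=2 * max(n - len(pool), 8))
            cand = cand[registries[chrom].mask_free(cand)]
            pool = np.unique(np.concatenate([pool, cand]))
        if len(pool) < n:
            raise PlacementError(f"could not place {n} SNVs on {chrom}")
        chosen = np.sort(rng.choice(pool, size=n, replace=False)) if n else pool[:0]
        for p in chosen.tolist():
            registries[chrom].add(p, p + 1)
        ref_bases = maternal[chrom][chosen]
        alt_bases = _other_base(rng, ref_bases)
        for pos, rb, ab in zip(chosen.tolist(), ref_bases.tolist(), alt_bases.tolist()):
            edits[chrom].append((pos, "snv", 1, ab))
            var_rows.append(dict(var_class="SNV", ref_chrom=chrom, ref_start=pos,
                                 ref_end=pos + 1, qry_chrom=chrom, length=1,
                                 ref_allele=chr(rb), alt_allele=chr(ab), kind="snv"))

    # --- apply edits to derive the paternal haplotype -----------------------
    paternal: dict[str, np.ndarray] = {}
    offsets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    qry_starts: dict[tuple[str, int], int] = {}  # (chrom, ref_start of op) -> qry pos
    for chrom, L in lengths.items():
        ops = sorted(edits[chrom], key=lambda t: t[0])
        pieces: list[np.ndarray] = []
        bounds = [0]
        offs = [0]
        cursor = 0
        out_len = 0
        src = maternal[chrom]
        for pos, kind, length, payload in ops:
            pieces.append(src[cursor:pos])
            out_len += pos - cursor
            qry_starts[(chrom, pos)] = out_len
            if kind == "snv":
                pieces.append(np.array([payload], dtype=np.uint8))
                out_len += 1
                cursor = pos + 1
            elif kind == "ins":
                pieces.append(payload)
                out_len += length
                cursor = pos
            elif kind == "del":
                cursor = pos + length
            elif kind == "inv":
                pieces.append(_revcomp(src[pos:pos + length]))
                out_len += length
                cursor = pos + length
            bounds.append(cursor)
            offs.append(out_len - cursor)
        pieces.append(src[cursor:])
        out_len += L - cursor
        paternal[chrom] = np.concatenate(pieces) if pieces else src.copy()
        offsets[chrom] = (np.asarray(bounds), np.asarray(offs))

    # qry coordinates for the truth table
    for row in var_rows:
        chrom = row["ref_chrom"]
        key_pos = row.get("target_pos", row["ref_start"])
        key_chrom = row["qry_chrom"] if "target_pos" in row else chrom
        q = qry_starts.get((key_chrom, key_pos))
        if q is None:  # pure deletion keyed on the source chromosome
            q = qry_starts.get((chrom, row["ref_start"]), row["ref_start"])
        row["qry_start"] = q
        if row["kind"] in ("deletion",):
            row["qry_end"] = q
        elif row["kind"] == "translocation" or row["kind"] == "duplication":
            row["qry_end"] = q + row["length"]
        elif row["kind"] == "insertion":
            row["qry_end"] = q + row["length"]
        else:  # snv, inversion
            row["qry_end"] = q + row["length"]

    variants = pd.DataFrame(var_rows)
    if variants.empty:
        variants = pd.DataFrame(columns=["var_class", "ref_chrom", "ref_start", "ref_end",
                                         "qry_chrom", "qry_start", "qry_end", "length",
                                         "ref_allele", "alt_allele", "kind"])

    # --- de novo mutations ---------------------------------------------------
    dnm_rng = substream(config.seed, "trio_dnms")
    total_bases = 2 * config.haploid_length
    n_dnm = int(dnm_rng.poisson(config.dnm_rate * total_bases))
    n_pat = int(dnm_rng.binomial(n_dnm, config.paternal_fraction)) if n_dnm else 0
    chrom_arr = np.array(chrom_names)
    probs = np.array([lengths[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()

    child_maternal = {c: maternal[c].copy() for c in maternal}
    child_paternal = {c: paternal[c].copy() for c in paternal}
    dnm_rows = []
    for origin, count in (("maternal", n_dnm - n_pat), ("paternal", n_pat)):
        placed = 0
        for _ in range(100 * max(count, 1)):
            if placed >= count:
                break
            chrom = str(dnm_rng.choice(chrom_arr, p=probs))
            pos = int(dnm_rng.integers(0, lengths[chrom]))
            if not registries[chrom].mask_free(np.array([pos]))[0]:
                continue
            registries[chrom].add(pos, pos + 1)
            bounds, offs = offsets[chrom]
            off = offs[np.searchsorted(bounds, pos, side="right") - 1]
            pos_pat = pos + int(off)
            ref = maternal[chrom][pos]
            alt = _other_base(dnm_rng, np.array([ref], dtype=np.uint8))[0]
            if origin == "maternal":
                child_maternal[chrom][pos] = alt
            else:
                child_paternal[chrom][pos_pat] = alt
            dnm_rows.append(dict(origin=origin, chrom=chrom, pos_mat=pos, pos_pat=pos_pat,
                                 ref=chr(ref), alt=chr(alt)))
            placed += 1
        if placed < count:
            raise PlacementError("could not place all DNMs without collisions")

    dnms = pd.DataFrame(dnm_rows, columns=["origin", "chrom", "pos_mat", "pos_pat", "ref", "alt"])

    return TrioGenomeTruth(
        config=config,
        maternal=maternal,
        paternal=paternal,
        child_maternal=child_maternal,
        child_paternal=child_paternal,
        variants=variants,
        dnms=dnms,
        roh=roh,
        edits=edits,
    )
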