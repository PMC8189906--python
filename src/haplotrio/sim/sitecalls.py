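"""Per-site trio genotype tables rendered on each parental reference.

Read evidence at every site of both references (the child's maternal- and
paternal-inherited sequences) is simulated for mother, father and child:
Poisson depth, binomial allele sampling, a small iid miscall rate, and a
heavy tail of per-individual "error hotspots" that emulate context-specific
systematic sequencing error. Genotypes are then called with a three-genotype
binomial likelihood model and a scaled log-likelihood-ratio genotype quality.

A planted maternal DNM renders as 0/0, 0/0, 0/1 on the paternal reference and
1/1, 1/1, 0/1 on the maternal reference (and symmetrically for paternal
DNMs), which is exactly the dual-reference discovery/validation design the
denovo module implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import substream
from .genomes import BASES, TrioGenomeTruth

__all__ = ["SiteCallTable", "TrioSiteTables", "simulate_site_calls"]

# genotype codes
HOMREF, HET, HOMALT, MISSING = 0, 1, 2, -1
HET_LIKE = 0.5
HOTSPOT_RATE = 1e-4
HOTSPOT_MULT = 50.0
HOTSPOT_CAP = 0.25

_REARRANGEMENTS = {"inversion", "translocation", "CNV", "inverted_translocation"}


@dataclass
class SiteCallTable:
    """Joint trio genotype table on one parental reference, one array per field."""

    reference: str  # 'maternal' or 'paternal'
    depth_mean: float
    columns: dict[str, dict[str, np.ndarray]] = field(repr=False, default_factory=dict)
    # columns[chrom] holds: gt_m/f/c (int8), dp_m/f/c (int32), alt_m/f/c (int32),
    # gq_m/f/c (float32)

    @property
    def chroms(self) -> list[str]:
        return list(self.columns)

    def n_sites(self) -> int:
        return sum(len(c["gt_c"]) for c in self.columns.values())


@dataclass
class TrioSiteTables:
    """Site-call tables on both references plus optional child pileups."""

    maternal: SiteCallTable
    paternal: SiteCallTable
    pileups: dict[str, dict[str, pd.DataFrame]] | None
    _offsets: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)

    def table(self, reference: str) -> SiteCallTable:
        return {"maternal": self.maternal, "paternal": self.paternal}[reference]

    def lift(self, reference: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Map positions on ``reference`` to the other reference (-1 if unmappable)."""
        positions = np.asarray(positions, dtype=np.int64)
        bounds, offs = self._offsets.get(chrom, (np.array([0]), np.array([0])))
        if reference == "maternal":
            idx = np.searchsorted(bounds, positions, side="right") - 1
            out = positions + offs[idx]
        else:
            pat_bounds = bounds + offs
            idx = np.searchsorted(pat_bounds, positions, side="right") - 1
            out = positions - offs[idx]
        other_len = {"maternal": self._len_pat, "paternal": self._len_mat}[reference]
        out[(out < 0) | (out >= other_len.get(chrom, 0))] = -1
        return out

    _len_mat: dict[str, int] = field(default_factory=dict, repr=False)
    _len_pat: dict[str, int] = field(default_factory=dict, repr=False)


def _genotype_tables(d_max: int, model_err: float) -> tuple[np.ndarray, np.ndarray]:
    """(gt, gq) lookup tables over all (depth, alt count) pairs up to ``d_max``."""
    e = max(model_err, 1e-6) / 3.0
    d = np.arange(d_max + 1, dtype=np.float64)[:, None]
    k = np.arange(d_max + 1, dtype=np.float64)[None, :]
    with np.errstate(invalid="ignore"):
        ll0 = k * np.log(e) + (d - k) * np.log1p(-e)
        ll1 = d * np.log(0.5)
        ll2 = k * np.log1p(-e) + (d - k) * np.log(e)
    gt = np.where(ll0 >= ll1, np.where(ll0 >= ll2, 0, 2),
                  np.where(ll1 >= ll2, 1, 2)).astype(np.int8)
    mx = np.maximum(np.maximum(ll0, ll1), ll2)
    mn = np.minimum(np.minimum(ll0, ll1), ll2)
    gq = np.minimum((2 * mx - (ll0 + ll1 + ll2 - mn)) * (10.0 / np.log(10.0)),
                    99.0).astype(np.float32)
    gt[0, :] = MISSING
    gq[0, :] = 0.0
    return gt, gq


def _genotype(d: np.ndarray, k: np.ndarray, model_err: float) -> tuple[np.ndarray, np.ndarray]:
    """Call genotypes from alt counts ``k`` of depth ``d``; return (gt, gq).

    Genotype and quality depend on (d, k) only, so both are precomputed as
    lookup tables and gathered — the per-site cost is two indexed reads.
    """
    d_max = int(d.max(initial=0))
    gt_tab, gq_tab = _genotype_tables(d_max, model_err)
    idx = d.astype(np.int64) * (d_max + 1) + k.astype(np.int64)
    return gt_tab.ravel()[idx], gq_tab.ravel()[idx]


def simulate_site_calls(
    truth: TrioGenomeTruth,
    depth_mean: float | None = None,
    base_error: float | None = None,
    seed: int | None = None,
    include_pileups: bool = True,
    hotspot_rate: float = HOTSPOT_RATE,
    hotspot_mult: float = HOTSPOT_MULT,
) -> TrioSiteTables:
    """Render trio genotype tables (and child pileups) on both references.

    Defaults for depth, error rate and seed come from ``truth.config``. Truth
    sets containing rearrangement classes are rejected: per-site tables are
    only meaningful on colinear references.
    """
    cfg = truth.config
    depth_mean = cfg.depth_mean if depth_mean is None else float(depth_mean)
    base_error = cfg.base_error if base_error is None else float(base_error)
    seed = cfg.seed if seed is None else int(seed)
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not 0.0 <= base_error < 0.25:
        raise ValueError("base_error must be in [0, 0.25): the genotype model is degenerate")
    if not truth.variants.empty and set(truth.variants["var_class"]) & _REARRANGEMENTS:
        raise ValueError(
            "site-call simulation requires a colinear truth set (SNVs/indels/DNMs only)"
        )

    rng = substream(seed, "site_calls")
    e_draw = base_error / 3.0
    p_hot = min(hotspot_mult * base_error, HOTSPOT_CAP)

    # offsets maternal -> paternal coordinates, from the recorded edits
    offsets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ops in truth.edits.items():
        bounds, offs, run = [0], [0], 0
        for pos, kind, length, _payload in sorted(ops, key=lambda t: t[0]):
            if kind == "ins":
                run += length
                bounds.append(pos)
            elif kind == "del":
                run -= length
                bounds.append(pos + length)
            else:
                continue
            offs.append(run)
        offsets[chrom] = (np.asarray(bounds), np.asarray(offs))

    # shared child read draws at DNM sites (same reads seen from both references)
    dnm_draws: dict[tuple[str, str], tuple[int, int]] = {}
    for row in truth.dnms.itertuples():
        d_c = int(rng.poisson(depth_mean))
        k_mat = int(rng.binomial(d_c, 0.5))  # reads carrying the maternal-haplotype allele
        dnm_draws[(row.chrom, f"{row.pos_mat}")] = (d_c, k_mat)

    tables: dict[str, SiteCallTable] = {}
    pileups: dict[str, dict[str, pd.DataFrame]] | None = {} if include_pileups else None
    for reference, seqs in (("maternal", truth.child_maternal), ("paternal", truth.child_paternal)):
        table = SiteCallTable(reference=reference, depth_mean=depth_mean)
        if include_pileups:
            pileups[reference] = {}
        for chrom, refseq in seqs.items():
            L = len(refseq)
            p_alt = {ind: np.full(L, e_draw, dtype=np.float32) for ind in "mfc"}

            variants = truth.variants
            if not variants.empty:
                snv = variants[(variants["var_class"] == "SNV") & (variants["ref_chrom"] == chrom)]
                pos = (snv["ref_start"] if reference == "maternal" else snv["qry_start"]).to_numpy()
                if reference == "maternal":
                    p_alt["m"][pos] = e_draw
                    p_alt["f"][pos] = 1.0 - e_draw
                else:
                    p_alt["m"][pos] = 1.0 - e_draw
                    p_alt["f"][pos] = e_draw
                p_alt["c"][pos] = HET_LIKE
                # indel footprints: ambiguous alignment, masked by a het-like smear
                ind = variants[variants["var_class"].str.endswith("indel")
                               & (variants["ref_chrom"] == chrom)]
                for r in ind.itertuples():
                    lo = r.ref_start if reference == "maternal" else r.qry_start
                    hi = max(r.ref_end if reference == "maternal" else r.qry_end, lo + 1)
                    lo, hi = max(lo - 1, 0), min(hi + 1, L)
                    for indiv in "mfc":
                        p_alt[indiv][lo:hi] = HET_LIKE

            dnm = truth.dnms[truth.dnms["chrom"] == chrom] if not truth.dnms.empty else None
            if dnm is not None and len(dnm):
                pos = (dnm["pos_mat"] if reference == "maternal" else dnm["pos_pat"]).to_numpy()
                same_ref = (dnm["origin"] == reference).to_numpy()
                # DNM on the haplotype this reference derives from: the reference
                # carries the new allele, both parents look 1/1.
                p_alt["m"][pos[same_ref]] = 1.0 - e_draw
                p_alt["f"][pos[same_ref]] = 1.0 - e_draw
                p_alt["m"][pos[~same_ref]] = e_draw
                p_alt["f"][pos[~same_ref]] = e_draw
                p_alt["c"][pos] = HET_LIKE

            cols: dict[str, np.ndarray] = {}
            base = np.float32(e_draw)
            for indiv in "mfc":
                d = rng.poisson(depth_mean, size=L).astype(np.int32)
                # scalar-p fast path for the hom-ref background, then sparse
                # redraws at variant sites and error hotspots
                k = rng.binomial(d, e_draw).astype(np.int32) if e_draw > 0 \
                    else np.zeros(L, dtype=np.int32)
                special = np.flatnonzero(p_alt[indiv] != base)
                if len(special):
                    k[special] = rng.binomial(d[special],
                                              p_alt[indiv][special].astype(np.float64))
                if hotspot_rate > 0 and p_hot > 0:
                    n_hot = rng.binomial(L, hotspot_rate)
                    hot = np.unique(rng.integers(0, L, size=n_hot))
                    hot = hot[p_alt[indiv][hot] == base]
                    if len(hot):
                        k[hot] = rng.binomial(d[hot], p_hot)
                cols[f"dp_{indiv}"] = d
                cols[f"alt_{indiv}"] = k

            # overwrite child draws at DNM sites with the shared reads
            if dnm is not None and len(dnm):
                for r in dnm.itertuples():
                    d_c, k_mat = dnm_draws[(r.chrom, f"{r.pos_mat}")]
                    p = r.pos_mat if reference == "maternal" else r.pos_pat
                    cols["dp_c"][p] = d_c
                    alt_is_mat_allele = (
                        (reference == "paternal") == (r.origin == "maternal")
                    )
                    cols["alt_c"][p] = k_mat if alt_is_mat_allele else d_c - k_mat

            for indiv in "mfc":
                gt, gq = _genotype(cols[f"dp_{indiv}"], cols[f"alt_{indiv}"], base_error)
                cols[f"gt_{indiv}"] = gt
                cols[f"gq_{indiv}"] = gq
            table.columns[chrom] = cols

            if include_pileups:
                ref_idx = np.searchsorted(BASES, refseq)
                alt_idx = (ref_idx + 1) % 4  # stand-in alternate base off variant sites
                depth = np.zeros((L, 4), dtype=np.int32)
                d, k = cols["dp_c"], cols["alt_c"]
                np.add.at(depth, (np.arange(L), ref_idx), d - k)
                np.add.at(depth, (np.arange(L), alt_idx), k)
                pileups[reference][chrom] = pd.DataFrame(
                    {"chrom": chrom, "pos": np.arange(L), "A": depth[:, 0],
                     "C": depth[:, 1], "G": depth[:, 2], "T": depth[:, 3]}
                )
        tables[reference] = table

    out = TrioSiteTables(maternal=tables["maternal"], paternal=tables["paternal"],
                         pileups=pileups)
    out._offsets = offsets
    out._len_mat = {c: len(s) for c, s in truth.child_maternal.items()}
    out._len_pat = {c: len(s) for c, s in truth.child_paternal.items()}
    return out
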