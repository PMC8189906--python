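"""Dual-reference trio de novo mutation calling and rate estimation.

With both parental haplotypes assembled independently, each serves as a
reference: a de novo mutation (DNM) inherited from one parent appears on the
OTHER parent's reference as parents 0/0 with a heterozygous child, and on its
own parent's reference as parents 1/1 with a heterozygous child. Requiring
both patterns (cross-validation) suppresses reference-specific artifacts
almost entirely.

The rate is

    mu = (M_mat + M_pat) / (C_mat (1 - a_mat) + C_pat (1 - a_pat))

where M are validated DNM counts by parent of origin, C are callable-site
counts per reference (both parents 0/0 and all three individuals passing the
depth, genotype-quality and parental-alternative-allele filters) and a
(alpha) is the fraction of TRUE heterozygous-child sites the genotype-quality
and allelic-balance filters would reject, estimated by binomial simulation.
The confidence interval is an exact (Garwood) Poisson interval on the summed
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .sim.sitecalls import HET, HOMALT, HOMREF, MISSING, SiteCallTable, TrioSiteTables

__all__ = [
    "TrioSiteCall",
    "FilterParams",
    "FilterResult",
    "MutationRateEstimate",
    "apply_site_filters",
    "call_candidates",
    "cross_validate_candidates",
    "compute_callability",
    "estimate_alpha",
    "estimate_rate",
    "run_trio_analysis",
]

# genotype codes re-exported for callers assembling tables by hand
assert (HOMREF, HET, HOMALT, MISSING) == (0, 1, 2, -1)


@dataclass(frozen=True)
class FilterParams:
    """Site-level filters; defaults are conventional trio-DNM settings."""

    gq_min: float = 20.0
    ab_range: tuple[float, float] = (0.3, 0.7)
    depth_factor: tuple[float, float] = (0.5, 2.0)  # times the individual's mean depth
    parental_alt_max: int = 0


@dataclass(frozen=True)
class TrioSiteCall:
    """Genotypes/depths/qualities of mother, father, child at one site."""

    reference: str
    chrom: str
    pos: int
    gt: tuple[int, int, int]  # (mother, father, child); -1 = missing
    depth: tuple[int, int, int]
    alt_depth: tuple[int, int, int]
    gq: tuple[float, float, float]
    mean_depth: tuple[float, float, float]


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    flags: tuple[str, ...]


def apply_site_filters(site: TrioSiteCall, params: FilterParams = FilterParams()) -> FilterResult:
    """Evaluate the depth / GQ / parental-alt / child-allelic-balance filters."""
    flags: list[str] = []
    lo_f, hi_f = params.depth_factor
    for who, d, mean in zip("mfc", site.depth, site.mean_depth):
        if not lo_f * mean <= d <= hi_f * mean:
            flags.append(f"depth_{who}")
    for who, q in zip("mfc", site.gq):
        if q < params.gq_min:
            flags.append(f"gq_{who}")
    for who, a in zip("mf", site.alt_depth[:2]):
        if a > params.parental_alt_max:
            flags.append(f"parental_alt_{who}")
    d_c, a_c = site.depth[2], site.alt_depth[2]
    ab = a_c / d_c if d_c > 0 else np.nan
    lo, hi = params.ab_range
    if not (d_c > 0 and lo <= ab <= hi):
        flags.append("allelic_balance")
    return FilterResult(passed=not flags, flags=tuple(flags))


def _mean_depths(table: SiteCallTable) -> dict[str, float]:
    means = {}
    for ind in "mfc":
        tot = n = 0
        for cols in table.columns.values():
            tot += int(cols[f"dp_{ind}"].sum())
            n += len(cols[f"dp_{ind}"])
        means[ind] = tot / max(n, 1)
    return means


def _masks(table: SiteCallTable, chrom: str, params: FilterParams,
           means: dict[str, float]) -> dict[str, np.ndarray]:
    cols = table.columns[chrom]
    lo_f, hi_f = params.depth_factor
    depth_ok = np.ones(len(cols["gt_c"]), dtype=bool)
    gq_ok = depth_ok.copy()
    for ind in "mfc":
        d = cols[f"dp_{ind}"]
        depth_ok &= (d >= lo_f * means[ind]) & (d <= hi_f * means[ind])
        gq_ok &= cols[f"gq_{ind}"] >= params.gq_min
    parent_alt_ok = ((cols["alt_m"] <= params.parental_alt_max)
                     & (cols["alt_f"] <= params.parental_alt_max))
    d_c = cols["dp_c"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(d_c > 0, cols["alt_c"] / np.maximum(d_c, 1), np.nan)
    lo, hi = params.ab_range
    ab_ok = (d_c > 0) & (ab >= lo) & (ab <= hi)
    return {"depth": depth_ok, "gq": gq_ok, "parent_alt": parent_alt_ok, "ab": ab_ok}


def call_candidates(table: SiteCallTable,
                    params: FilterParams = FilterParams()) -> pd.DataFrame:
    """DNM candidates on one reference: parents 0/0, child 0/1, all filters passed.

    The hypothesised parent of origin is the parent whose haplotype is NOT
    the mapping reference (a maternal DNM is discovered on the paternal
    reference and vice versa). Sites with a missing genotype are skipped.
    """
    origin = {"paternal": "maternal", "maternal": "paternal"}[table.reference]
    means = _mean_depths(table)
    rows = []
    for chrom, cols in table.columns.items():
        m = _masks(table, chrom, params, means)
        cand = ((cols["gt_m"] == HOMREF) & (cols["gt_f"] == HOMREF)
                & (cols["gt_c"] == HET)
                & m["depth"] & m["gq"] & m["parent_alt"] & m["ab"])
        for pos in np.flatnonzero(cand):
            rows.append(dict(reference=table.reference, chrom=chrom, pos=int(pos),
                             origin=origin))
    return pd.DataFrame(rows, columns=["reference", "chrom", "pos", "origin"])


def cross_validate_candidates(
    candidates: pd.DataFrame,
    tables: TrioSiteTables,
    params: FilterParams = FilterParams(),
) -> pd.DataFrame:
    """Keep candidates showing 1/1, 1/1, 0/1 (and passing filters) on the other reference.

    Returns the candidate table with ``validated`` and ``reason`` columns;
    sites that cannot be mapped to the other reference are rejected as
    'unmappable'.
    """
    out = candidates.copy()
    out["validated"] = False
    out["reason"] = ""
    means_cache = {ref: _mean_depths(tables.table(ref)) for ref in ("maternal", "paternal")}
    for idx, row in candidates.iterrows():
        other_ref = {"maternal": "paternal", "paternal": "maternal"}[row["reference"]]
        other = tables.table(other_ref)
        lifted = tables.lift(row["reference"], row["chrom"], np.array([row["pos"]]))[0]
        if lifted < 0 or row["chrom"] not in other.columns:
            out.loc[idx, "reason"] = "unmappable"
            continue
        cols = other.columns[row["chrom"]]
        p = int(lifted)
        if not (cols["gt_m"][p] == HOMALT and cols["gt_f"][p] == HOMALT
                and cols["gt_c"][p] == HET):
            out.loc[idx, "reason"] = "pattern_mismatch"
            continue
        means = means_cache[other_ref]
        site = TrioSiteCall(
            reference=other_ref, chrom=row["chrom"], pos=p,
            gt=(int(cols["gt_m"][p]), int(cols["gt_f"][p]), int(cols["gt_c"][p])),
            depth=(int(cols["dp_m"][p]), int(cols["dp_f"][p]), int(cols["dp_c"][p])),
            alt_depth=(int(cols["alt_m"][p]), int(cols["alt_f"][p]), int(cols["alt_c"][p])),
            gq=(float(cols["gq_m"][p]), float(cols["gq_f"][p]), float(cols["gq_c"][p])),
            mean_depth=(means["m"], means["f"], means["c"]),
        )
        res = apply_site_filters(site, params)
        # parents are genuinely 1/1 on this reference; the parental-alt filter
        # targets stray alternative reads in 0/0 parents and does not apply
        flags = tuple(f for f in res.flags if not f.startswith("parental_alt"))
        if flags:
            out.loc[idx, "reason"] = "filters:" + ",".join(flags)
            continue
        out.loc[idx, "validated"] = True
        out.loc[idx, "reason"] = "validated"
    return out


def compute_callability(table: SiteCallTable,
                        params: FilterParams = FilterParams()) -> int:
    """Sites with both parents 0/0 and all three individuals passing depth/GQ/alt filters."""
    means = _mean_depths(table)
    total = 0
    for chrom in table.columns:
        cols = table.columns[chrom]
        m = _masks(table, chrom, params, means)
        ok = ((cols["gt_m"] == HOMREF) & (cols["gt_f"] == HOMREF)
              & m["depth"] & m["gq"] & m["parent_alt"])
        total += int(ok.sum())
    return total


def estimate_alpha(
    params: FilterParams = FilterParams(),
    depth_mean: float = 30.0,
    n_sim: int = 100_000,
    seed: int = 0,
    base_error: float = 1e-3,
    fixed_depth: int | None = None,
) -> float:
    """Fraction of true heterozygous-child sites lost to the GQ and allelic-balance filters.

    Simulates binomial allele sampling at the reference's depth model (Poisson
    around ``depth_mean``, or a fixed depth) conditional on the depth filter,
    and applies the heterozygous-call GQ and allelic-balance filters.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    if depth_mean <= 0:
        raise ValueError("degenerate depth model: depth_mean must be > 0")
    rng = substream(seed, "alpha")
    if fixed_depth is not None:
        d = np.full(n_sim, int(fixed_depth))
    else:
        d = rng.poisson(depth_mean, size=n_sim)
    lo_f, hi_f = params.depth_factor
    d = d[(d >= lo_f * depth_mean) & (d <= hi_f * depth_mean) & (d > 0)]
    if len(d) == 0:
        raise ValueError("depth model incompatible with the depth filter")
    k = rng.binomial(d, 0.5)
    ab = k / d
    lo, hi = params.ab_range
    rejected = (ab < lo) | (ab > hi)
    if params.gq_min > 0:
        e = max(base_error, 1e-6) / 3.0
        ll_het = d * np.log(0.5)
        ll_hom = np.maximum(k * np.log(e) + (d - k) * np.log1p(-e),
                            k * np.log1p(-e) + (d - k) * np.log(e))
        gq = (ll_het - ll_hom) * (10.0 / np.log(10.0))
        rejected |= gq < params.gq_min
    return float(rejected.mean())


@dataclass(frozen=True)
class MutationRateEstimate:
    """Per-generation mutation rate with its exact Poisson 95% CI."""

    mutations_maternal: int
    mutations_paternal: int
    callability_maternal: float
    callability_paternal: float
    alpha_maternal: float
    alpha_paternal: float
    mu: float
    ci95: tuple[float, float]
    paternal_maternal_ratio: float = field(default=np.nan)

    @property
    def total_mutations(self) -> int:
        return self.mutations_maternal + self.mutations_paternal


def _garwood_ci(n: int, conf: float = 0.95) -> tuple[float, float]:
    a = 1.0 - conf
    lower = 0.0 if n == 0 else 0.5 * stats.chi2.ppf(a / 2, 2 * n)
    upper = 0.5 * stats.chi2.ppf(1 - a / 2, 2 * n + 2)
    return lower, upper


def estimate_rate(
    mutations_maternal: int,
    mutations_paternal: int,
    callability_maternal: float,
    callability_paternal: float,
    alpha_maternal: float = 0.0,
    alpha_paternal: float = 0.0,
) -> MutationRateEstimate:
    """mu = (M_mat + M_pat) / (C_mat (1 - a_mat) + C_pat (1 - a_pat))."""
    denom = (callability_maternal * (1.0 - alpha_maternal)
             + callability_paternal * (1.0 - alpha_paternal))
    if denom <= 0:
        raise ValueError("callability-corrected denominator must be > 0")
    n = mutations_maternal + mutations_paternal
    lo, hi = _garwood_ci(n)
    ratio = (mutations_paternal / mutations_maternal
             if mutations_maternal > 0 else np.inf if mutations_paternal else np.nan)
    return MutationRateEstimate(
        mutations_maternal=mutations_maternal,
        mutations_paternal=mutations_paternal,
        callability_maternal=callability_maternal,
        callability_paternal=callability_paternal,
        alpha_maternal=alpha_maternal,
        alpha_paternal=alpha_paternal,
        mu=n / denom,
        ci95=(lo / denom, hi / denom),
        paternal_maternal_ratio=ratio,
    )


def run_trio_analysis(
    tables: TrioSiteTables,
    params: FilterParams = FilterParams(),
    cross_validate: bool = True,
    alpha_n_sim: int = 100_000,
    seed: int = 0,
    base_error: float = 1e-3,
) -> dict:
    """Full dual-reference pipeline: candidates, validation, callability, alpha, mu."""
    cands = pd.concat(
        [call_candidates(tables.maternal, params), call_candidates(tables.paternal, params)],
        ignore_index=True,
    )
    if cross_validate:
        cands = cross_validate_candidates(cands, tables, params)
        final = cands[cands["validated"]]
    else:
        cands = cands.assign(validated=True, reason="not_cross_validated")
        final = cands
    m_mat = int((final["origin"] == "maternal").sum())
    m_pat = int((final["origin"] == "paternal").sum())
    c_mat = compute_callability(tables.maternal, params)
    c_pat = compute_callability(tables.paternal, params)
    a_mat = estimate_alpha(params, tables.maternal.depth_mean, alpha_n_sim, seed,
                           base_error)
    a_pat = estimate_alpha(params, tables.paternal.depth_mean, alpha_n_sim, seed + 1,
                           base_error)
    est = estimate_rate(m_mat, m_pat, c_mat, c_pat, a_mat, a_pat)
    return {"candidates": cands, "estimate": est}
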