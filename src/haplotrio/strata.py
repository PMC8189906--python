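"""Gametologue divergence, evolutionary strata and molecular-clock dating.

X- and Y-linked copies of a gene (gametologues) stop recombining when their
region is recruited into the sex-differentiation region; synonymous
divergence (dS) between the copies then accumulates with time, so pairs
sharing a recombination-suppression age form an "evolutionary stratum" of
similar dS, and dS grows with distance from the pseudoautosomal boundary.

dN/dS uses the Nei–Gojobori (1986) pathway-counting method with the
Jukes–Cantor multiple-hit correction; strata are a contiguous least-squares
segmentation of dS along the X; dating applies the molecular clock
T = d / (2 r) for a per-year rate r (or a per-generation rate mu with
generation time g via r = mu / g).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DnDsResult",
    "DatingEstimate",
    "compute_dn_ds",
    "correlate_ds_position",
    "assign_strata",
    "date_divergence",
]

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    _CODON_TABLE[_a + _b + _c] = _AMINO[_i]

STOPS = {c for c, aa in _CODON_TABLE.items() if aa == "*"}


@dataclass(frozen=True)
class DnDsResult:
    """Pairwise NG86 estimates; ``dn``/``ds`` are NaN when Jukes–Cantor saturates."""

    dn: float
    ds: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float

    def __iter__(self):
        return iter((self.dn, self.ds))


def _syn_sites(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts of one codon (stops count as non-syn)."""
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if _CODON_TABLE[alt] == aa and alt not in STOPS:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous difference counts over mutational pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0.0
        blocked = False
        steps = []
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            cur = nxt
        for a, b in steps:
            if _CODON_TABLE[a] == _CODON_TABLE[b]:
                sd += 1.0
            else:
                nd += 1.0
        intermediates = [b for _a, b in steps[:-1]]
        if any(i in STOPS for i in intermediates):
            blocked = True
        paths.append((blocked, sd, nd))
    usable = [(s, n) for blocked, s, n in paths if not blocked]
    if not usable:
        usable = [(s, n) for _bl, s, n in paths]
    sd = sum(s for s, _n in usable) / len(usable)
    nd = sum(n for _s, n in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan  # saturated: correction undefined
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def compute_dn_ds(x_cds: str, y_cds: str) -> DnDsResult:
    """NG86 pairwise dN/dS with Jukes–Cantor correction for two aligned CDS.

    Both sequences must be gap-free, equal-length, in frame and free of
    internal stop codons; a trailing stop codon (present in both) is trimmed.
    """
    x_cds, y_cds = x_cds.upper(), y_cds.upper()
    if len(x_cds) != len(y_cds):
        raise ValueError("CDS lengths differ")
    if len(x_cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    if "-" in x_cds or "-" in y_cds:
        raise ValueError("gapped alignments are not supported")
    codons_x = [x_cds[i:i + 3] for i in range(0, len(x_cds), 3)]
    codons_y = [y_cds[i:i + 3] for i in range(0, len(y_cds), 3)]
    if codons_x and codons_x[-1] in STOPS and codons_y[-1] in STOPS:
        codons_x, codons_y = codons_x[:-1], codons_y[:-1]
    for codons in (codons_x, codons_y):
        for c in codons:
            if c in STOPS:
                raise ValueError("internal stop codon")
            if any(b not in "ACGT" for b in c):
                raise ValueError(f"non-ACGT symbol in codon {c!r}")

    s1 = sum(_syn_sites(c)[0] for c in codons_x)
    s2 = sum(_syn_sites(c)[0] for c in codons_y)
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * len(codons_x) - s_sites
    sd = nd = 0.0
    for cx, cy in zip(codons_x, codons_y):
        a, b = _pathway_counts(cx, cy)
        sd += a
        nd += b
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return DnDsResult(dn=_jukes_cantor(pn), ds=_jukes_cantor(ps),
                      n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd)


def correlate_ds_position(pairs: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of dS against X position over non-excluded pairs.

    Expects columns ``ds`` and ``x_pos``. Returns (r, two-sided p); both are
    NaN when either variable has zero variance.
    """
    sub = pairs.loc[np.isfinite(pairs["ds"]) & np.isfinite(pairs["x_pos"])]
    if len(sub) < 3:
        raise ValueError("need at least 3 pairs with finite dS")
    if sub["ds"].nunique() < 2 or sub["x_pos"].nunique() < 2:
        return math.nan, math.nan
    r, p = stats.pearsonr(sub["x_pos"], sub["ds"])
    return float(r), float(p)


def _segment_cost(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squares of values[i:j] from prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def _dp_segmentation(values: np.ndarray, k: int) -> list[int]:
    """Optimal contiguous k-segmentation (least squares); returns boundary indices."""
    n = len(values)
    prefix = np.concatenate([[0.0], np.cumsum(values)])
    prefix2 = np.concatenate([[0.0], np.cumsum(values ** 2)])
    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for seg in range(1, k + 1):
        for j in range(seg, n + 1):
            for i in range(seg - 1, j):
                c = cost[seg - 1, i] + _segment_cost(prefix, prefix2, i, j)
                if c < cost[seg, j] - 1e-12:
                    cost[seg, j] = c
                    back[seg, j] = i
    bounds = [n]
    j = n
    for seg in range(k, 0, -1):
        j = back[seg, j]
        bounds.append(j)
    return bounds[::-1]  # [0, b1, ..., n]


def assign_strata(
    pairs: pd.DataFrame,
    k: int | None = None,
    max_k: int = 6,
    ds_floor: float = 0.02,
    bic_penalty: float = 2.0,
) -> pd.DataFrame:
    """Segment gametologue pairs into evolutionary strata along the X.

    Pairs flagged as recent intra-species duplications (column
    ``recent_duplicate``) with dS below ``ds_floor`` are excluded before
    segmentation. Pairs are ordered by ``x_pos`` and segmented contiguously to
    minimise within-stratum dS variance; ``k`` is chosen by a BIC-style
    penalty when not supplied. Labels S1..Sk run from highest to lowest mean
    dS (oldest to youngest stratum).
    """
    out = pairs.copy()
    out["stratum"] = ""
    excluded = pd.Series(False, index=out.index)
    if "recent_duplicate" in out.columns:
        excluded = out["recent_duplicate"].fillna(False).astype(bool) & (out["ds"] < ds_floor)
    excluded |= ~np.isfinite(out["ds"])
    out.loc[excluded, "stratum"] = "excluded"
    sub = out.loc[~excluded].sort_values("x_pos")
    n = len(sub)
    if n == 0:
        return out
    values = sub["ds"].to_numpy(dtype=float)
    if k is not None:
        if k > n:
            raise ValueError(f"k={k} exceeds the number of usable pairs ({n})")
        bounds = _dp_segmentation(values, k)
    else:
        best = None
        # variance floor (1% of the dS range) keeps the penalty effective when
        # within-stratum noise is tiny relative to between-strata separation
        floor = (0.01 * (values.max() - values.min())) ** 2 + 1e-12
        for kk in range(1, min(max_k, n) + 1):
            b = _dp_segmentation(values, kk)
            prefix = np.concatenate([[0.0], np.cumsum(values)])
            prefix2 = np.concatenate([[0.0], np.cumsum(values ** 2)])
            sse = sum(_segment_cost(prefix, prefix2, b[i], b[i + 1]) for i in range(kk))
            bic = n * math.log(sse / n + floor) + bic_penalty * kk * math.log(n)
            if best is None or bic < best[0]:
                best = (bic, b)
        bounds = best[1]
    seg_means = []
    seg_of_pair = np.zeros(n, dtype=int)
    for s in range(len(bounds) - 1):
        lo, hi = bounds[s], bounds[s + 1]
        seg_means.append(values[lo:hi].mean())
        seg_of_pair[lo:hi] = s
    order = np.argsort(np.argsort(-np.asarray(seg_means)))  # rank by decreasing mean dS
    labels = [f"S{order[s] + 1}" for s in seg_of_pair]
    out.loc[sub.index, "stratum"] = labels
    return out


@dataclass(frozen=True)
class DatingEstimate:
    """Clock dating of a divergence ``d`` under one or more substitution rates."""

    divergence: float
    entries: tuple[dict, ...]  # each: rate_per_year, years, source
    years_min: float
    years_max: float


def date_divergence(
    d: float,
    rates: Iterable[float | tuple[float, float]],
) -> DatingEstimate:
    """T = d / (2 r) per rate; a (mu, g) tuple is a per-generation rate with
    generation time g years, converted as r = mu / g."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    entries = []
    for spec in rates:
        if isinstance(spec, tuple):
            mu, g = spec
            if mu <= 0 or g <= 0:
                raise ValueError("per-generation rate and generation time must be > 0")
            r = mu / g
            source = f"mu={mu:g}/generation, g={g:g} yr"
        else:
            r = float(spec)
            if r <= 0:
                raise ValueError("rate must be > 0")
            source = f"r={r:g}/yr"
        entries.append({"rate_per_year": r, "years": d / (2.0 * r), "source": source})
    if not entries:
        raise ValueError("at least one rate is required")
    years = [e["years"] for e in entries]
    return DatingEstimate(divergence=d, entries=tuple(entries),
                          years_min=min(years), years_max=max(years))
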