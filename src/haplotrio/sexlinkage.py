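"""Sex-linked sequence identification and collapsed-region reconstruction.

A female (XX) and a male (XY) sample are sequenced to similar genome-wide
depth; after peak normalization of each sample, the female-to-male (F/M)
per-window depth ratio is ~1 on autosomes, ~2 on the X (two female copies vs
one male copy) and ~0 on the Y (female carries none). Windows with ratio in
[1.5, 2.5] are X-linked and in [0.0, 0.3] Y-linked; scaffold calls follow a
window majority, with a terminal ratio-1 block on an otherwise-Y scaffold
annotated as pseudoautosomal (PAR) rather than defeating the call.

Y scaffolds missed by the strict depth filter are rescued from Hi-C contact
strength: scaffolds whose interactions with the Y backbone are significantly
stronger than with autosomes/X (two-sided Wilcoxon rank-sum, BH-FDR) are
called Y-linked. Collapsed duplications are rebuilt by the "longest rule":
repeatedly place the candidate contig with the longest non-overlapping
backbone match, fill the rest from the backbone, and separate placed contigs
with exactly 1,000 N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoverageTrack",
    "DecollapseCandidate",
    "normalize_coverage",
    "classify_windows",
    "call_scaffold_linkage",
    "hic_rescue",
    "longest_rule_decollapse",
    "X_RANGE",
    "Y_RANGE",
]

X_RANGE = (1.5, 2.5)
Y_RANGE = (0.0, 0.3)
RATIO_CAP = 10.0
GAP_N = 1000


@dataclass
class CoverageTrack:
    """Per-window depths of one sample, peak-normalized."""

    windows: pd.DataFrame  # chrom, start, end, depth, norm_depth
    peak: float  # modal per-window raw depth


def normalize_coverage(windows: pd.DataFrame, depth_col: str = "depth",
                       bin_frac: float = 0.05) -> CoverageTrack:
    """Divide depths by the modal (peak) depth.

    The peak is the centre of the highest bin of a histogram of nonzero
    window depths with bin width ``bin_frac`` times the median depth — the
    mode of the depth distribution is dominated by the diploid background
    and is robust to sex-chromosome and collapsed windows, unlike the mean.
    """
    depth = windows[depth_col].to_numpy(dtype=float)
    nonzero = depth[depth > 0]
    if len(nonzero) == 0:
        raise ValueError("cannot peak-normalize an all-zero coverage track")
    med = float(np.median(nonzero))
    width = max(bin_frac * med, 1e-9)
    edges = np.arange(0.0, nonzero.max() + 2 * width, width)
    counts, _ = np.histogram(nonzero, bins=edges)
    peak = float(edges[np.argmax(counts)] + width / 2.0)
    out = windows.copy()
    out["norm_depth"] = depth / peak
    return CoverageTrack(windows=out, peak=peak)


def classify_windows(
    female: CoverageTrack,
    male: CoverageTrack,
    x_range: tuple[float, float] = X_RANGE,
    y_range: tuple[float, float] = Y_RANGE,
) -> pd.DataFrame:
    """Per-window F/M ratio and class ('X', 'Y' or 'unassigned').

    Both tracks must cover identical windows. Zero-male windows take a
    one-read-equivalent pseudocount in the denominator, and ratios are
    capped at 10.
    """
    f, m = female.windows, male.windows
    if len(f) != len(m) or not (
        (f["chrom"].to_numpy() == m["chrom"].to_numpy()).all()
        and (f["start"].to_numpy() == m["start"].to_numpy()).all()
    ):
        raise ValueError("female and male tracks must cover identical windows")
    fn = f["norm_depth"].to_numpy(dtype=float)
    mn = m["norm_depth"].to_numpy(dtype=float)
    pseudo = 1.0 / male.peak  # one read of depth, in normalized units
    ratio = np.where(mn > 0, fn / np.maximum(mn, 1e-300), fn / pseudo)
    ratio = np.minimum(ratio, RATIO_CAP)
    cls = np.full(len(ratio), "unassigned", dtype=object)
    cls[(ratio >= x_range[0]) & (ratio <= x_range[1])] = "X"
    cls[(ratio >= y_range[0]) & (ratio <= y_range[1])] = "Y"
    out = f[["chrom", "start", "end"]].copy()
    out["female_norm"] = fn
    out["male_norm"] = mn
    out["fm_ratio"] = ratio
    out["window_class"] = cls
    return out


def call_scaffold_linkage(
    windows: pd.DataFrame,
    majority: float = 0.8,
    min_windows: int = 10,
    par_band: tuple[float, float] = (0.7, 1.3),
    par_min_run: int = 25,
) -> pd.DataFrame:
    """Per-scaffold linkage calls with PAR annotation.

    A scaffold is X or Y when >= ``majority`` of its windows share that
    class, and 'autosome' when >= ``majority`` are unassigned with a median
    ratio near 1. A terminal run (>= ``par_min_run`` windows) of ratio~1
    windows on an otherwise sex-linked scaffold is annotated as PAR and
    excluded from the majority computation instead of defeating the call.
    """
    rows = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        n = len(sub)
        if n < min_windows:
            rows.append((chrom, "no_call", "fewer_than_min_windows", None))
            continue

        def vote(s: pd.DataFrame):
            frac = s["window_class"].value_counts(normalize=True)
            for c in ("X", "Y"):
                if frac.get(c, 0.0) >= majority:
                    return c
            if (frac.get("unassigned", 0.0) >= majority
                    and par_band[0] <= s["fm_ratio"].median() <= par_band[1]):
                return "autosome"
            return None

        # terminal PAR-like blocks (ratio ~ 1) are annotated, not voted
        parlike = ((sub["fm_ratio"] >= par_band[0])
                   & (sub["fm_ratio"] <= par_band[1])).to_numpy()
        lead = int(np.argmin(parlike)) if not parlike.all() else len(parlike)
        trail = int(np.argmin(parlike[::-1])) if not parlike.all() else 0
        par_intervals = []
        core = sub
        if lead >= par_min_run:
            par_intervals.append((int(sub.iloc[0]["start"]), int(sub.iloc[lead - 1]["end"])))
            core = core.iloc[lead:]
        if trail >= par_min_run:
            par_intervals.append((int(sub.iloc[n - trail]["start"]), int(sub.iloc[-1]["end"])))
            core = core.iloc[: len(core) - trail]
        if par_intervals and len(core) >= min_windows:
            call = vote(core)
            if call in ("X", "Y"):
                rows.append((chrom, call, "window_majority_with_PAR", par_intervals))
                continue
        call = vote(sub)
        if call is not None:
            rows.append((chrom, call, "window_majority", None))
        else:
            rows.append((chrom, "no_call", "no_majority", None))
    return pd.DataFrame(rows, columns=["scaffold", "call", "reason", "par_intervals"])


def hic_rescue(
    interactions: pd.DataFrame,
    q_cut: float = 0.01,
    min_values: int = 5,
) -> pd.DataFrame:
    """Rescue Y-linked scaffolds from Hi-C interaction strength.

    ``interactions`` needs columns scaffold, to_autosomes_x, to_y (vectors).
    Scaffolds with more than ``min_values`` strengths on both sides are
    tested (two-sided Wilcoxon rank-sum); after Benjamini–Hochberg
    correction a scaffold is rescued iff q < ``q_cut`` AND its median Y
    strength exceeds its median autosome/X strength.
    """
    out = interactions.copy()
    n_aut = out["to_autosomes_x"].map(len)
    n_y = out["to_y"].map(len)
    out["excluded"] = (n_aut <= min_values) | (n_y <= min_values)
    pvals = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples()):
        if row.excluded:
            continue
        res = stats.mannwhitneyu(row.to_y, row.to_autosomes_x, alternative="two-sided")
        pvals[i] = res.pvalue
    out["p_value"] = pvals
    qvals = np.full(len(out), np.nan)
    tested = ~out["excluded"].to_numpy()
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out["q_value"] = qvals
    median_up = np.array([
        (np.median(r.to_y) > np.median(r.to_autosomes_x)) if not r.excluded else False
        for r in out.itertuples()
    ])
    out["rescued"] = tested & (out["q_value"].to_numpy() < q_cut) & median_up
    return out


@dataclass(frozen=True)
class DecollapseCandidate:
    """A de-collapsed contig with its best mapping interval on the backbone."""

    contig_id: str
    sequence: str
    start: int  # mapped interval on the backbone, 0-based half-open
    end: int
    match_len: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")
        if self.match_len > self.end - self.start:
            raise ValueError("match length cannot exceed the mapped interval")


def longest_rule_decollapse(
    backbone: str,
    candidates: Sequence[DecollapseCandidate],
    gap_n: int = GAP_N,
) -> tuple[str, list[DecollapseCandidate]]:
    """Greedy longest-match reconstruction of a collapsed scaffold.

    Iteratively selects the candidate with the longest backbone match that
    does not overlap a previously selected interval (ties: earlier backbone
    start), orders the selected contigs by backbone position, fills
    unselected backbone stretches from the backbone itself, and separates
    each placed contig from its neighbours by exactly ``gap_n`` N.

    Returns the reconstructed sequence and the selected candidates in
    backbone order.
    """
    ids = [c.contig_id for c in candidates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate candidate contig ids")
    for c in candidates:
        if c.end > len(backbone):
            raise ValueError(f"candidate {c.contig_id} maps outside the backbone")
    chosen: list[DecollapseCandidate] = []
    remaining = sorted(candidates, key=lambda c: (-c.match_len, c.start, c.contig_id))
    occupied: list[tuple[int, int]] = []
    for cand in remaining:
        if all(cand.end <= s or cand.start >= e for s, e in occupied):
            chosen.append(cand)
            occupied.append((cand.start, cand.end))
    chosen.sort(key=lambda c: c.start)
    if not chosen:
        return backbone, []
    pieces: list[str] = []
    cursor = 0
    for cand in chosen:
        if cand.start > cursor:
            pieces.append(backbone[cursor:cand.start])
        pieces.append(cand.sequence)
        cursor = cand.end
    if cursor < len(backbone):
        pieces.append(backbone[cursor:])
    gap = "N" * gap_n
    return gap.join(p for p in pieces if p), chosen
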