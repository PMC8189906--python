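"""Confident-SNP set construction, the pileup π statistic, and error partitioning.

A confident heterozygous-SNP set is assembled from three independent callers:
setA (whole-genome alignment of the two haplotypes), setB and setC (two
read-mapping pipelines). Set1 = B ∩ C, Set2 = A ∪ Set1, and Set3 keeps the
Set2 sites that survive a pileup filter: adequate linked-read depth and no
"complex" base composition. A site is complex when its pileup heterozygosity

    π = 2 (A·T + A·C + A·G + T·C + T·G + C·G) / (D (D − 1)),   D = A+T+C+G,

exceeds 0.4 while the third-highest base depth exceeds 5 — i.e. far from the
clean ~50/50 two-allele split a true heterozygous site shows.

Assembly errors are partitioned into sequencing vs polishing errors from an
evidence chain of consensus bases across assembly stages (see
``classify_evidence_chain`` for the decision table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

__all__ = [
    "PileupSite",
    "SnpSets",
    "EvidenceChain",
    "compute_pi",
    "classify_pileup_site",
    "build_snp_sets",
    "classify_evidence_chain",
    "estimate_error_rates",
]


@dataclass(frozen=True)
class PileupSite:
    """Base depths of one pileup column."""

    a: int
    c: int
    g: int
    t: int
    chrom: str = ""
    pos: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t) < 0:
            raise ValueError("base depths must be >= 0")

    @property
    def depth(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def depths_sorted(self) -> list[int]:
        return sorted((self.a, self.c, self.g, self.t), reverse=True)


def compute_pi(site: PileupSite) -> float:
    """Pileup heterozygosity: the probability two sampled reads disagree.

    Pair terms are products of base depths; defined for total depth >= 2.
    """
    d = site.depth
    if d < 2:
        raise ValueError("pi is undefined for depth < 2")
    a, c, g, t = site.a, site.c, site.g, site.t
    cross = a * t + a * c + a * g + t * c + t * g + c * g
    return 2.0 * cross / (d * (d - 1))


def classify_pileup_site(
    site: PileupSite,
    min_depth: int = 10,
    pi_cut: float = 0.4,
    third_depth_cut: int = 5,
) -> str:
    """Return 'low_depth', 'complex' or 'kept'.

    Complexity needs BOTH a high π and a substantial third allele: a clean
    50/50 het site has π ≈ 0.5 but a third-highest depth of ~0.
    """
    if site.depth < min_depth:
        return "low_depth"
    if compute_pi(site) > pi_cut and site.depths_sorted[2] > third_depth_cut:
        return "complex"
    return "kept"


@dataclass(frozen=True)
class SnpSets:
    """The derived SNP sets; ``set1`` = B ∩ C, ``set2`` = A ∪ set1, ``set3`` filtered."""

    set_a: frozenset
    set_b: frozenset
    set_c: frozenset
    set1: frozenset
    set2: frozenset
    set3: frozenset


def _check_allele_consistency(*site_sets: Iterable[Hashable]) -> None:
    """Keys of form (chrom, pos, ref, alt) must not conflict at one locus."""
    by_locus: dict[tuple, tuple] = {}
    for s in site_sets:
        for key in s:
            if isinstance(key, tuple) and len(key) >= 4:
                locus, alleles = key[:2], key[2:]
                seen = by_locus.setdefault(locus, alleles)
                if seen != alleles:
                    raise ValueError(f"inconsistent alleles at {locus}: {seen} vs {alleles}")


def build_snp_sets(
    set_a: Iterable[Hashable],
    set_b: Iterable[Hashable],
    set_c: Iterable[Hashable],
    pileups: Mapping[Hashable, PileupSite] | None = None,
    aligned_sites: Iterable[Hashable] | None = None,
) -> SnpSets:
    """Assemble Set1/Set2/Set3 from the three caller outputs.

    Set3 drops Set2 sites whose pileup fails ``classify_pileup_site`` (low
    depth or complex) and, when ``aligned_sites`` is given, sites absent from
    the haplotype-alignment support.
    """
    a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
    _check_allele_consistency(a, b, c)
    set1 = b & c
    set2 = a | set1
    keep = set()
    aligned = frozenset(aligned_sites) if aligned_sites is not None else None
    for key in set2:
        if aligned is not None and key not in aligned:
            continue
        if pileups is not None:
            site = pileups.get(key)
            if site is None or classify_pileup_site(site) != "kept":
                continue
        keep.add(key)
    return SnpSets(set_a=a, set_b=b, set_c=c, set1=set1, set2=set2, set3=frozenset(keep))


@dataclass(frozen=True)
class EvidenceChain:
    """Consensus base at each assembly stage for one haplotype at one site."""

    raw: str
    corrected: str
    pre_polish: str
    post_polish: str
    short: str

    def __post_init__(self) -> None:
        for b in (self.raw, self.corrected, self.pre_polish, self.post_polish, self.short):
            if b not in "ACGTN" or len(b) != 1:
                raise ValueError(f"chain entries must be one of A,C,G,T,N; got {b!r}")


def classify_evidence_chain(chain: EvidenceChain) -> str:
    """Partition a chain into sequencing_error / polishing_error / true_variant / unresolved.

    Decision table (checked in order; any N at a decisive position falls
    through to 'unresolved'):

    1. true_variant      — post-polish == corrected == short.
    2. sequencing_error  — post-polish == raw but conflicts with both the
                           corrected-read and short-read consensus.
    3. polishing_error   — pre-polish matched the short-read consensus and
                           post-polish departed from it.
    4. unresolved        — anything else.
    """
    raw, cor = chain.raw, chain.corrected
    pre, post, short = chain.pre_polish, chain.post_polish, chain.short
    if "N" not in (post, cor, short) and post == cor == short:
        return "true_variant"
    if ("N" not in (post, raw, cor, short)
            and post == raw and post != cor and post != short):
        return "sequencing_error"
    if "N" not in (pre, post, short) and pre == short and post != short:
        return "polishing_error"
    return "unresolved"


def estimate_error_rates(
    classified: Iterable[str] | Mapping[str, int],
    assayed_bases: float,
) -> dict[str, float]:
    """Per-class error rates: class count / assayed bases."""
    if assayed_bases <= 0:
        raise ValueError("assayed_bases must be > 0")
    if isinstance(classified, Mapping):
        counts = dict(classified)
    else:
        counts = {}
        for c in classified:
            counts[c] = counts.get(c, 0) + 1
    return {
        "sequencing_error_rate": counts.get("sequencing_error", 0) / assayed_bases,
        "polishing_error_rate": counts.get("polishing_error", 0) / assayed_bases,
        "assayed_bases": float(assayed_bases),
        "counts": counts,
    }
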