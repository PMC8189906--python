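"""Pileup site QC with the π statistic and assembly-error partitioning.

Shows the worked complex-site pileup, the three-caller SNP-set algebra
(Set1 = B ∩ C, Set2 = A ∪ Set1, Set3 = pileup-filtered), and the evidence-
chain classification of sequencing vs polishing errors on simulated chains.
"""

from haplotrio.sim import simulate_evidence_chains
from haplotrio.siteqc import (
    EvidenceChain,
    PileupSite,
    build_snp_sets,
    classify_evidence_chain,
    classify_pileup_site,
    compute_pi,
    estimate_error_rates,
)

site = PileupSite(a=20, t=20, c=14, g=0)
print(f"pileup A:20 T:20 C:14 G:0 -> pi = {compute_pi(site):.4f}, "
      f"class = {classify_pileup_site(site)}")
print("(pi > 0.4 with a 14-read third allele: no clean haplotype call is "
      "possible, so the site is dropped)")

clean = PileupSite(a=15, t=15, c=0, g=0)
print(f"pileup A:15 T:15 -> pi = {compute_pi(clean):.4f}, "
      f"class = {classify_pileup_site(clean)} (a clean 50/50 het)")

sets = build_snp_sets({1, 2, 3}, {2, 3, 4}, {3, 4, 5})
print(f"\nSNP sets: Set1 = {sorted(sets.set1)}, Set2 = {sorted(sets.set2)}")

n_assayed = 1_000_000
chains = simulate_evidence_chains(34, 37, 500, depth=30, seed=17)
classes = [classify_evidence_chain(EvidenceChain(r.raw, r.corrected, r.pre_polish,
                                                 r.post_polish, r.short))
           for r in chains.itertuples()]
rates = estimate_error_rates(classes, n_assayed)
print(f"\nplanted 34 sequencing / 37 polishing errors over {n_assayed:,} bases:")
print(f"estimated sequencing-error rate: {rates['sequencing_error_rate']:.2e}")
print(f"estimated polishing-error rate:  {rates['polishing_error_rate']:.2e}")
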