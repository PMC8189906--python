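"""Sex-linked scaffold identification from coverage ratios and Hi-C rescue.

Simulates a female (XX) and male (XY) sample at 30x over an autosome, an X
and a Y, classifies 5-kb windows by the peak-normalized F/M depth ratio
(~2 on X, ~0 on Y, ~1 on autosomes), calls scaffolds by window majority,
then rescues Y-linked unplaced scaffolds by Wilcoxon tests on Hi-C contact
strengths, and finally rebuilds a collapsed region with the longest rule.
"""

from haplotrio.sexlinkage import (
    DecollapseCandidate,
    call_scaffold_linkage,
    classify_windows,
    hic_rescue,
    longest_rule_decollapse,
    normalize_coverage,
)
from haplotrio.sim import Chromosome, simulate_coverage_tracks, simulate_hic_interactions

layout = [Chromosome("auto1", 10_000_000), Chromosome("chrX", 2_000_000, "X"),
          Chromosome("chrY", 1_000_000, "Y")]
cov = simulate_coverage_tracks(layout, female_depth=30, male_depth=30,
                               window_bp=5000, seed=3)
female = normalize_coverage(cov.rename(columns={"female_depth": "depth"}))
male = normalize_coverage(cov.rename(columns={"male_depth": "depth"}))
windows = classify_windows(female, male)
calls = call_scaffold_linkage(windows)
print("scaffold calls from the F/M coverage ratio:")
print(calls[["scaffold", "call", "reason"]].to_string(index=False))

spec = {f"unplaced_y{i}": True for i in range(3)}
spec |= {f"unplaced_a{i}": False for i in range(6)}
hic = simulate_hic_interactions(spec, bias=3.0, n_values=50, seed=4)
rescued = hic_rescue(hic)
print("\nHi-C rescue (two-sided Wilcoxon, BH-FDR q < 0.01):")
print(rescued[["scaffold", "p_value", "q_value", "rescued"]]
      .to_string(index=False, float_format=lambda x: f"{x:.2e}"))

backbone = "A" * 9000
cands = [DecollapseCandidate("ctg_long", "C" * 6000, 0, 6000, 6000),
         DecollapseCandidate("ctg_mid", "G" * 5000, 3000, 8000, 5000),
         DecollapseCandidate("ctg_short", "T" * 3000, 6000, 9000, 3000)]
seq, chosen = longest_rule_decollapse(backbone, cands)
print(f"\nlongest-rule selection: {[c.contig_id for c in chosen]} "
      f"(the 5-kb match overlaps the 6-kb winner and is skipped)")
print(f"reconstructed scaffold: {len(seq):,} bp with "
      f"{seq.count('N' * 1000)} gap(s) of exactly 1,000 N")
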