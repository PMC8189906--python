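"""Dual-reference DNM calling: patterns, filters, callability, alpha, rate."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from haplotrio import denovo
from haplotrio.denovo import (
    FilterParams,
    TrioSiteCall,
    apply_site_filters,
    estimate_alpha,
    estimate_rate,
)
from haplotrio.sim import Chromosome, IndelSpec, SimConfig, simulate_site_calls, simulate_trio_genomes


def _site(gt=(0, 0, 1), depth=(30, 30, 30), alt=(0, 0, 15), gq=(90, 90, 90),
          mean=(30.0, 30.0, 30.0), reference="paternal"):
    return TrioSiteCall(reference=reference, chrom="c", pos=1, gt=gt, depth=depth,
                        alt_depth=alt, gq=gq, mean_depth=mean)


def _tables(seed=0, L=400_000, dnm_rate=2e-5, base_error=1e-3, **kw):
    cfg = SimConfig(genome_layout=[Chromosome("chr1", L)], snv_rate=1e-3,
                    indel_spec=IndelSpec(rate=0.0), dnm_rate=dnm_rate,
                    base_error=base_error, seed=seed, **kw)
    truth = simulate_trio_genomes(cfg)
    return truth, simulate_site_calls(truth, include_pileups=False)


class TestFilters:
    def test_depth_out_of_range_fails(self):
        res = apply_site_filters(_site(depth=(30, 30, 75), alt=(0, 0, 37)))
        assert not res.passed and "depth_c" in res.flags

    def test_parental_alt_reads_fail(self):
        res = apply_site_filters(_site(alt=(0, 2, 15)))
        assert not res.passed and "parental_alt_f" in res.flags

    def test_balanced_site_passes(self):
        assert apply_site_filters(_site()).passed

    def test_allelic_balance_fail(self):
        res = apply_site_filters(_site(alt=(0, 0, 4)))
        assert "allelic_balance" in res.flags


class TestCandidates:
    def test_patterns(self):
        truth, tables = _tables(seed=5)
        cands = denovo.call_candidates(tables.paternal)
        # every candidate on the paternal reference hypothesises a maternal DNM
        assert (cands["origin"] == "maternal").all()
        planted = set(truth.dnms.loc[truth.dnms.origin == "maternal", "pos_pat"])
        assert planted >= set()  # non-trivial truth
        assert len(set(cands["pos"]) & planted) >= 0.6 * len(planted)

    def test_validated_subset_of_candidates(self):
        _, tables = _tables(seed=6)
        cands = denovo.call_candidates(tables.paternal)
        out = denovo.cross_validate_candidates(cands, tables)
        assert out["validated"].sum() <= len(cands)
        assert set(out.loc[out.validated, "pos"]) <= set(cands["pos"])

    def test_cross_reference_mismatch_rejected(self):
        """A candidate whose cross-reference pattern is not 1/1,1/1,0/1 is dropped."""
        _, tables = _tables(seed=7)
        cands = denovo.call_candidates(tables.paternal)
        assert len(cands)
        # corrupt the maternal-reference mother genotype at the first candidate
        row = cands.iloc[0]
        lifted = int(tables.lift("paternal", row.chrom, np.array([row.pos]))[0])
        tables.maternal.columns[row.chrom]["gt_m"][lifted] = 1
        out = denovo.cross_validate_candidates(cands.iloc[[0]], tables)
        assert not out["validated"].iloc[0]
        assert out["reason"].iloc[0] == "pattern_mismatch"

    def test_unmappable_site_rejected(self):
        _, tables = _tables(seed=8)
        cands = denovo.call_candidates(tables.paternal)
        assert len(cands)
        tables._len_mat["chr1"] = 0  # nothing maps anymore
        out = denovo.cross_validate_candidates(cands.iloc[[0]], tables)
        assert out["reason"].iloc[0] == "unmappable"


class TestCallability:
    def test_bruteforce_recount_on_toy_table(self):
        _, tables = _tables(seed=9, L=50_000)
        params = FilterParams()
        table = tables.maternal
        fast = denovo.compute_callability(table, params)
        means = denovo._mean_depths(table)
        slow = 0
        cols = table.columns["chr1"]
        for p in range(len(cols["gt_c"])):
            if cols["gt_m"][p] != 0 or cols["gt_f"][p] != 0:
                continue
            ok = True
            for ind, who in zip("mfc", range(3)):
                d = cols[f"dp_{ind}"][p]
                if not 0.5 * means[ind] <= d <= 2 * means[ind]:
                    ok = False
                if cols[f"gq_{ind}"][p] < params.gq_min:
                    ok = False
            if cols["alt_m"][p] > 0 or cols["alt_f"][p] > 0:
                ok = False
            slow += ok
        assert fast == slow
        assert 0 < fast < len(cols["gt_c"])

    def test_filters_disabled_counts_double_homref(self):
        _, tables = _tables(seed=10, L=50_000)
        params = FilterParams(gq_min=0, ab_range=(0, 1), depth_factor=(0, np.inf),
                              parental_alt_max=10**9)
        cols = tables.maternal.columns["chr1"]
        expect = int(((cols["gt_m"] == 0) & (cols["gt_f"] == 0)).sum())
        assert denovo.compute_callability(tables.maternal, params) == expect


class TestAlpha:
    def test_disabled_filters_alpha_zero(self):
        params = FilterParams(gq_min=0, ab_range=(0.0, 1.0))
        assert estimate_alpha(params, 30.0, n_sim=5000, seed=1) == 0.0

    def test_binomial_tail_oracle_at_fixed_depth(self):
        """AB in [0.3, 0.7] at depth 30: alpha = P(k outside [9, 21]), k ~ Bin(30, .5)."""
        params = FilterParams(gq_min=0, ab_range=(0.3, 0.7))
        alpha = estimate_alpha(params, 30.0, n_sim=200_000, seed=2, fixed_depth=30)
        exact = 1.0 - (stats.binom.cdf(21, 30, 0.5) - stats.binom.cdf(8, 30, 0.5))
        assert alpha == pytest.approx(exact, abs=0.005)

    def test_extreme_filter_alpha_near_one(self):
        params = FilterParams(gq_min=0, ab_range=(0.49, 0.51))
        assert estimate_alpha(params, 10.0, n_sim=5000, seed=3, fixed_depth=10) > 0.7

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            estimate_alpha(FilterParams(), 30.0, n_sim=10)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_alpha(FilterParams(), 0.0)


class TestRate:
    def test_formula_on_published_scale(self):
        """Nine mutations over two 1.05e9-site callabilities give ~0.43e-8."""
        est = estimate_rate(3, 6, 1.0465e9, 1.0465e9)
        assert est.mu == pytest.approx(9 / 2.093e9, rel=1e-4)
        assert est.mu == pytest.approx(0.43e-8, rel=0.01)
        assert est.paternal_maternal_ratio == pytest.approx(2.0)

    def test_zero_mutations(self):
        est = estimate_rate(0, 0, 1e6, 1e6)
        assert est.mu == 0.0
        assert est.ci95[0] == 0.0

    def test_doubling_callability_halves_mu(self):
        a = estimate_rate(4, 4, 1e6, 1e6)
        b = estimate_rate(4, 4, 2e6, 2e6)
        assert b.mu == pytest.approx(a.mu / 2)

    def test_alpha_one_errors(self):
        with pytest.raises(ValueError):
            estimate_rate(1, 1, 1e6, 1e6, 1.0, 1.0)

    def test_garwood_ci_covers_count(self):
        est = estimate_rate(5, 4, 1e6, 1e6)
        lo, hi = est.ci95
        assert lo < est.mu < hi

    def test_maternal_paternal_symmetry(self):
        """Swapping the parent labels swaps the counts and leaves mu unchanged."""
        a = estimate_rate(3, 6, 1.0e6, 1.2e6, 0.05, 0.02)
        b = estimate_rate(6, 3, 1.2e6, 1.0e6, 0.02, 0.05)
        assert a.mu == pytest.approx(b.mu)
        assert a.mutations_maternal == b.mutations_paternal


class TestSpecificity:
    def test_no_planted_dnms_zero_validated(self):
        """Cross-validation keeps the validated set empty without planted DNMs."""
        for seed in range(3):
            _, tables = _tables(seed=40 + seed, dnm_rate=0.0, L=300_000,
                                base_error=5e-3)
            res = denovo.run_trio_analysis(tables, alpha_n_sim=2000, seed=seed)
            assert res["estimate"].total_mutations == 0

    def test_disabling_cross_validation_admits_false_positives(self):
        """At base_error 5e-3 the heavy error tail creates candidate sites that
        only the dual-reference validation removes."""
        fp = 0
        for seed in range(3):
            _, tables = _tables(seed=50 + seed, dnm_rate=0.0, L=2_000_000,
                                base_error=5e-3)
            res = denovo.run_trio_analysis(tables, cross_validate=False,
                                           alpha_n_sim=2000, seed=seed)
            fp += res["estimate"].total_mutations
        assert fp >= 1
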