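"""Coverage-ratio classification, Hi-C rescue and longest-rule de-collapse."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplotrio.sexlinkage import (
    DecollapseCandidate,
    call_scaffold_linkage,
    classify_windows,
    hic_rescue,
    longest_rule_decollapse,
    normalize_coverage,
)
from haplotrio.sim import simulate_coverage_tracks, simulate_hic_interactions

from conftest import sexlink_layout


def _tracks(seed, female=30, male=30, window=5000, noise=0.0):
    cov = simulate_coverage_tracks(sexlink_layout(), female, male, window,
                                   seed=seed, noise_floor=noise)
    f = normalize_coverage(cov.rename(columns={"female_depth": "depth"}))
    m = normalize_coverage(cov.rename(columns={"male_depth": "depth"}))
    return cov, f, m


class TestNormalize:
    def test_modal_window_normalizes_to_one(self):
        rng = np.random.default_rng(0)
        depth = rng.poisson(30, 4000).astype(float)
        track = normalize_coverage(pd.DataFrame(
            {"chrom": "c", "start": np.arange(4000), "end": np.arange(4000) + 1,
             "depth": depth}))
        assert track.peak == pytest.approx(30, abs=1.5)
        mode_windows = track.windows.loc[np.isclose(depth, 30), "norm_depth"]
        assert np.allclose(mode_windows, 1.0, atol=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        depth = rng.poisson(25, 2000).astype(float)
        df = pd.DataFrame({"chrom": "c", "start": np.arange(2000),
                           "end": np.arange(2000) + 1, "depth": depth})
        a = normalize_coverage(df)
        b = normalize_coverage(df.assign(depth=depth * 7))
        assert np.allclose(a.windows.norm_depth, b.windows.norm_depth, rtol=1e-6)

    def test_all_zero_track_errors(self):
        df = pd.DataFrame({"chrom": "c", "start": [0], "end": [1], "depth": [0.0]})
        with pytest.raises(ValueError, match="all-zero"):
            normalize_coverage(df)


class TestClassify:
    def test_ratio_bands(self):
        cov, f, m = _tracks(seed=2)
        w = classify_windows(f, m)
        merged = w.merge(cov[["chrom", "start", "chrom_class"]], on=["chrom", "start"])
        x = merged[merged.chrom_class == "X"]
        y = merged[merged.chrom_class == "Y"]
        auto = merged[merged.chrom_class == "autosome"]
        assert (x.window_class == "X").mean() >= 0.99
        assert (y.window_class == "Y").mean() >= 0.99
        assert (auto.window_class == "unassigned").mean() >= 0.99

    def test_class_partition_and_scale_invariance(self):
        cov, f, m = _tracks(seed=3)
        w1 = classify_windows(f, m)
        f2 = normalize_coverage(
            cov.rename(columns={"female_depth": "depth"}).assign(
                depth=lambda d: d.depth * 11))
        m2 = normalize_coverage(
            cov.rename(columns={"male_depth": "depth"}).assign(
                depth=lambda d: d.depth * 11))
        w2 = classify_windows(f2, m2)
        assert (w1.window_class == w2.window_class).all()
        assert set(w1.window_class) <= {"X", "Y", "unassigned"}

    def test_mismatched_windows_error(self):
        cov, f, m = _tracks(seed=4)
        with pytest.raises(ValueError, match="identical windows"):
            classify_windows(f, normalize_coverage(
                m.windows.iloc[:-1].rename(columns={"norm_depth": "drop"})
                .rename(columns={"depth": "depth"})))


class TestScaffoldCalls:
    def test_majority_calls(self):
        cov, f, m = _tracks(seed=5)
        calls = call_scaffold_linkage(classify_windows(f, m)).set_index("scaffold")
        assert calls.loc["chrX", "call"] == "X"
        assert calls.loc["chrY", "call"] == "Y"
        assert calls.loc["auto1", "call"] == "autosome"

    def test_terminal_par_block_annotated_on_y_scaffold(self):
        """A leading ratio~1 block on an otherwise-Y scaffold yields Y + PAR."""
        n_par, n_y = 100, 400
        w = pd.DataFrame({
            "chrom": "scaf", "start": np.arange(n_par + n_y) * 2000,
            "end": (np.arange(n_par + n_y) + 1) * 2000,
            "female_norm": 1.0, "male_norm": 1.0,
            "fm_ratio": np.r_[np.full(n_par, 1.0), np.full(n_y, 0.05)],
            "window_class": ["unassigned"] * n_par + ["Y"] * n_y,
        })
        calls = call_scaffold_linkage(w)
        row = calls.iloc[0]
        assert row.call == "Y"
        assert row.reason == "window_majority_with_PAR"
        assert row.par_intervals == [(0, n_par * 2000)]

    def test_no_majority_no_call(self):
        w = pd.DataFrame({
            "chrom": "s", "start": np.arange(20) * 5000,
            "end": (np.arange(20) + 1) * 5000,
            "female_norm": 1.0, "male_norm": 1.0,
            "fm_ratio": [2.0] * 10 + [0.9] * 10,
            "window_class": ["X"] * 10 + ["unassigned"] * 10,
        })
        assert call_scaffold_linkage(w).iloc[0].call == "no_call"

    def test_too_few_windows_no_call_with_reason(self):
        w = pd.DataFrame({
            "chrom": "s", "start": np.arange(5) * 5000,
            "end": (np.arange(5) + 1) * 5000,
            "female_norm": 1.0, "male_norm": 0.5,
            "fm_ratio": 2.0, "window_class": "X",
        })
        row = call_scaffold_linkage(w).iloc[0]
        assert row.call == "no_call" and row.reason == "fewer_than_min_windows"


class TestHicRescue:
    def test_biased_scaffolds_rescued_nulls_not(self):
        spec = {f"y{i}": True for i in range(10)} | {f"n{i}": False for i in range(50)}
        hic = simulate_hic_interactions(spec, bias=3.0, n_values=50, seed=6)
        out = hic_rescue(hic).set_index("scaffold")
        assert out.loc[[f"y{i}" for i in range(10)], "rescued"].all()
        assert not out.loc[[f"n{i}" for i in range(50)], "rescued"].any()

    def test_five_interaction_values_excluded(self):
        hic = simulate_hic_interactions({"a": True, "b": True}, bias=3.0,
                                        n_values={"a": 5, "b": 50}, seed=7)
        out = hic_rescue(hic).set_index("scaffold")
        assert out.loc["a", "excluded"] and not out.loc["a", "rescued"]
        assert out.loc["b", "rescued"]

    def test_null_fdr_control(self):
        """Under the null, the rescued fraction stays at or below q_cut."""
        hic = simulate_hic_interactions({f"s{i}": False for i in range(1000)},
                                        bias=1.0, n_values=30, seed=8)
        # truth flag off: no bias anywhere; test against held q_cut
        out = hic_rescue(hic, q_cut=0.01)
        assert out.rescued.mean() <= 0.01


class TestLongestRule:
    def _c(self, cid, start, end, match=None, seq=None):
        return DecollapseCandidate(cid, seq or "X" * (end - start), start, end,
                                   match if match is not None else end - start)

    def test_overlapping_candidates_longest_wins(self):
        """6-kb and overlapping 5-kb plus disjoint 3-kb: picks {6 kb, 3 kb} with
        a single 1,000-N junction between adjacent placed contigs."""
        backbone = "A" * 9000
        cands = [self._c("six", 0, 6000, seq="C" * 6000),
                 self._c("five", 3000, 8000, seq="G" * 5000),
                 self._c("three", 6000, 9000, seq="T" * 3000)]
        seq, chosen = longest_rule_decollapse(backbone, cands)
        assert [c.contig_id for c in chosen] == ["six", "three"]
        assert seq == "C" * 6000 + "N" * 1000 + "T" * 3000
        assert seq.count("N" * 1000) == 1

    def test_no_candidates_backbone_unchanged(self):
        assert longest_rule_decollapse("ACGT" * 100, []) == ("ACGT" * 100, [])

    def test_single_spanning_candidate_no_gaps(self):
        backbone = "A" * 5000
        seq, chosen = longest_rule_decollapse(
            backbone, [self._c("one", 0, 5000, seq="G" * 5000)])
        assert seq == "G" * 5000 and "N" not in seq

    def test_backbone_fill_between_contigs(self):
        backbone = "A" * 10_000
        seq, _ = longest_rule_decollapse(
            backbone, [self._c("a", 0, 2000, seq="C" * 2000),
                       self._c("b", 8000, 10_000, seq="G" * 2000)])
        assert seq == "C" * 2000 + "N" * 1000 + "A" * 6000 + "N" * 1000 + "G" * 2000

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            longest_rule_decollapse("A" * 100, [self._c("x", 0, 10),
                                                self._c("x", 20, 30)])

    def test_candidate_outside_backbone_error(self):
        with pytest.raises(ValueError, match="outside"):
            longest_rule_decollapse("A" * 100, [self._c("x", 50, 200)])

    @staticmethod
    def _verify_longest_rule(cands, chosen_ids):
        """Independent step-by-step verifier of the greedy longest rule."""
        remaining = list(cands)
        occupied = []
        order = []
        while True:
            free = [c for c in remaining
                    if all(c.end <= s or c.start >= e for s, e in occupied)]
            if not free:
                break
            best = sorted(free, key=lambda c: (-c.match_len, c.start, c.contig_id))[0]
            order.append(best.contig_id)
            occupied.append((best.start, best.end))
            remaining.remove(best)
        return sorted(order) == sorted(chosen_ids)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, derandomize=True)
    def test_matches_exhaustive_verifier_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        cands = []
        for i in range(n):
            start = int(rng.integers(0, 9000))
            end = start + int(rng.integers(1, 1000))
            cands.append(DecollapseCandidate(f"c{i}", "A" * (end - start),
                                             start, end, end - start))
        seq, chosen = longest_rule_decollapse("G" * 10_000, cands)
        assert self._verify_longest_rule(cands, [c.contig_id for c in chosen])
        # every N run is exactly 1,000 long
        import re
        for m in re.finditer(r"N+", seq):
            assert m.end() - m.start() == 1000
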