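"""SV classification, read validation, ROH detection and the het summary."""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
import pytest

from haplotrio.hetspectrum import (
    AlignmentBlock,
    classify_svs,
    detect_roh,
    summarize_heterozygosity,
    validate_sv_with_reads,
)
from haplotrio.hetspectrum.variants import VariantRecord
from haplotrio.sim.genomes import BASES, _revcomp


def _B(rc, rs, re_, qc, qs, qe, orient="forward"):
    return AlignmentBlock(rc, rs, re_, qc, qs, qe, orient)


class TestClassify:
    def test_collinear_reverse_block_is_inversion(self):
        blocks = [_B("c", 0, 5000, "c", 0, 5000),
                  _B("c", 5000, 7000, "c", 5000, 7000, "reverse"),
                  _B("c", 7000, 12000, "c", 7000, 12000)]
        out = classify_svs(blocks)
        assert [v.var_class for v in out] == ["inversion"]
        assert out[0].ref_start == 5000 and out[0].length == 2000

    def test_cross_chromosome_forward_block_is_translocation(self):
        blocks = [_B("c1", 0, 5000, "c1", 0, 5000),
                  _B("c1", 5000, 6000, "c2", 3000, 4000),
                  _B("c1", 6000, 9000, "c1", 5000, 8000)]
        out = classify_svs(blocks)
        assert [v.var_class for v in out] == ["translocation"]
        assert out[0].qry_chrom == "c2"

    def test_relocated_reverse_block_is_inverted_translocation(self):
        blocks = [_B("c1", 0, 5000, "c1", 0, 5000),
                  _B("c1", 5000, 6000, "c2", 3000, 4000, "reverse"),
                  _B("c1", 6000, 9000, "c1", 5000, 8000)]
        out = classify_svs(blocks)
        assert [v.var_class for v in out] == ["inverted_translocation"]

    def test_query_segment_matching_two_ref_loci_is_cnv(self):
        """One query interval aligned to two disjoint reference loci."""
        blocks = [_B("c", 0, 9000, "c", 0, 9000),
                  _B("c", 2000, 3000, "c", 6500, 7500)]
        out = classify_svs(sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start)))
        cnv = [v for v in out if v.var_class == "CNV"]
        assert len(cnv) == 1
        assert cnv[0].copy_count == 2
        assert (cnv[0].ref_start, cnv[0].ref_end) == (2000, 3000)

    def test_junction_gap_is_large_indel(self):
        blocks = [_B("c", 0, 5000, "c", 0, 5000),
                  _B("c", 5200, 9000, "c", 5000, 8800)]
        out = classify_svs(blocks)
        assert [v.var_class for v in out] == ["large_indel"]
        assert out[0].kind == "deletion" and out[0].length == 200

    def test_balanced_junction_below_threshold_silent(self):
        blocks = [_B("c", 0, 5000, "c", 0, 5000),
                  _B("c", 5030, 9000, "c", 5030, 9000)]
        assert classify_svs(blocks) == []

    def test_unsorted_input_errors(self):
        blocks = [_B("c", 5000, 9000, "c", 5000, 9000),
                  _B("c", 0, 4000, "c", 0, 4000)]
        with pytest.raises(ValueError, match="sorted"):
            classify_svs(blocks)

    def test_each_junction_single_class_on_generated_truth(self, sv_truth, sv_blocks):
        """Planted inversion/translocation/CNV/large-indel counts all recovered."""
        out = classify_svs(sv_blocks)
        found = collections.Counter(v.var_class for v in out)
        planted = sv_truth.variants.var_class.value_counts().to_dict()
        for cls in ("inversion", "translocation", "CNV", "inverted_translocation",
                    "large_indel"):
            assert found.get(cls, 0) == planted.get(cls, 0), cls


class TestReadSupport:
    @pytest.fixture()
    def sv_scene(self):
        rng = np.random.default_rng(8)
        mat = BASES[rng.integers(0, 4, 6000)]
        pat = np.concatenate([mat[:3000], _revcomp(mat[3000:4000]), mat[4000:]])
        sv = VariantRecord("inversion", "c", 3000, 4000, "c", 3000, 4000, 1000,
                           kind="inversion")
        return {"c": mat}, {"c": pat}, sv

    def test_spanning_read_supports(self, sv_scene):
        mat, pat, sv = sv_scene
        read = pat["c"][2500:4500].tobytes().decode()
        status = validate_sv_with_reads(sv, mat, pat, long_reads=[read])
        assert status == "read_supported"

    def test_failed_read_but_linked_reads_support(self, sv_scene):
        mat, pat, sv = sv_scene
        rng = np.random.default_rng(9)
        junk = BASES[rng.integers(0, 4, 2000)].tobytes().decode()
        status = validate_sv_with_reads(sv, mat, pat, long_reads=[junk],
                                        linked_read_count=12)
        assert status == "linked_read_supported"

    def test_failed_read_and_low_linked_reads_rejected(self, sv_scene):
        mat, pat, sv = sv_scene
        rng = np.random.default_rng(10)
        junk = BASES[rng.integers(0, 4, 2000)].tobytes().decode()
        status = validate_sv_with_reads(sv, mat, pat, long_reads=[junk],
                                        linked_read_count=1)
        assert status == "rejected"

    def test_no_evidence_unresolved(self, sv_scene):
        mat, pat, sv = sv_scene
        assert validate_sv_with_reads(sv, mat, pat) == "unresolved"

    def test_breakpoint_near_contig_end_unresolved(self):
        rng = np.random.default_rng(11)
        mat = {"c": BASES[rng.integers(0, 4, 1000)]}
        sv = VariantRecord("large_indel", "c", 100, 300, "c", 100, 100, 200,
                           kind="deletion")
        read = mat["c"][:600].tobytes().decode()
        assert validate_sv_with_reads(sv, mat, mat, long_reads=[read]) == "unresolved"


class TestRoh:
    def _positions(self, rng, length, rate, holes):
        pos = np.sort(rng.choice(length, size=rng.poisson(rate * length),
                                 replace=False))
        for start, end in holes:
            pos = pos[(pos < start) | (pos >= end)]
        return pos

    def test_planted_runs_recovered_and_short_run_suppressed(self):
        """An 8-Mb hole is recovered (>=95% overlap); a 0.5-Mb hole never is."""
        rng = np.random.default_rng(12)
        L = 30_000_000
        holes = [(3_000_000, 11_000_000), (20_000_000, 20_500_000)]
        pos = self._positions(rng, L, 1e-3, holes)
        roh = detect_roh({"chr1": pos}, {"chr1": L})
        assert len(roh) == 1
        r = roh.iloc[0]
        overlap = min(r.end, 11_000_000) - max(r.start, 3_000_000)
        assert overlap >= 0.95 * 8_000_000
        assert (r.end - r.start) >= 1_000_000

    def test_variant_free_genome_one_roh_per_chromosome(self):
        roh = detect_roh({"c1": [], "c2": []},
                         {"c1": 2_000_000, "c2": 1_500_000})
        assert roh.chrom.tolist() == ["c1", "c2"]
        assert (roh.end - roh.start).tolist() == [2_000_000, 1_500_000]

    def test_all_intervals_respect_min_length(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pos = np.sort(rng.integers(0, 10_000_000, size=rng.integers(0, 3000)))
            roh = detect_roh({"c": pos}, {"c": 10_000_000})
            if len(roh):
                assert ((roh.end - roh.start) >= 1_000_000).all()

    def test_bad_window_errors(self):
        with pytest.raises(ValueError):
            detect_roh({"c": []}, {"c": 1000}, scan_window=0)


class TestSummary:
    def test_snv_only_rate(self):
        vs = [VariantRecord("SNV", "c", i, i + 1, "c", i, i + 1, 1)
              for i in range(1300)]
        s = summarize_heterozygosity(vs, aligned_length=1_000_000)
        assert s.snv_percent == pytest.approx(0.13)
        assert s.overall_percent == pytest.approx(0.13)

    def test_overall_includes_indel_and_sv_bases(self):
        vs = [VariantRecord("SNV", "c", i, i + 1, "c", i, i + 1, 1)
              for i in range(1300)]
        vs.append(VariantRecord("large_indel", "c", 5000, 17300, "c", 5000, 5000,
                                12300, kind="deletion"))
        s = summarize_heterozygosity(vs, aligned_length=1_000_000)
        assert s.overall_percent == pytest.approx(1.36)
        assert s.snv_percent == pytest.approx(0.13)

    def test_no_variants_zero(self):
        s = summarize_heterozygosity([], aligned_length=1000)
        assert s.snv_percent == 0.0 and s.overall_percent == 0.0

    def test_monotone_in_added_classes(self):
        base = [VariantRecord("SNV", "c", 1, 2, "c", 1, 2, 1)]
        extra = base + [VariantRecord("inversion", "c", 10, 50, "c", 10, 50, 40,
                                      kind="inversion")]
        a = summarize_heterozygosity(base, 1000).overall_rate
        b = summarize_heterozygosity(extra, 1000).overall_rate
        assert b >= a

    def test_density_tracks_window_sizes(self):
        vs = [VariantRecord("SNV", "c", 600_000, 600_001, "c", 0, 1, 1)]
        s = summarize_heterozygosity(vs, 2_000_000, chrom_lengths={"c": 2_000_000})
        snv_track = s.density_tracks["SNV"]
        assert (snv_track.end - snv_track.start).max() == 500_000
        assert snv_track.loc[snv_track.start == 500_000, "count"].item() == 1
        assert (s.density_tracks["large_indel"].end
                - s.density_tracks["large_indel"].start).max() == 1_000_000
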