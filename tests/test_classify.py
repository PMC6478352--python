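"""Error filters and the five-way classification rules."""

import numpy as np
import pandas as pd
import pytest

from hatseq.classify import (CATEGORIES, InsertionCall, chimera_polyA_filter,
                             classify_kr, classify_knr, classify_somatic,
                             classify_unassembled, classify_unk,
                             improper_alignment_filter, is_polyA_chimera,
                             local_sv_filter, merge_shifted_signals,
                             misalignment_filter, run_cascade)
from hatseq.config import FilterConfig
from hatseq.peakcall import Peak, PeakFeatures
from hatseq.readproc import parse_contigs
from hatseq.simdata import generate_contigs, plan_truth

CFG = FilterConfig()


def make_peak(chrom="chr1", start=1000, end=1200, strand="+", rpm=50.0,
              signal_starts=(1000,), signal_depths=(5,), overlap_family="",
              overlap_width=0, signal_count=None):
    f = PeakFeatures(rpm=rpm, width=end - start,
                     signal_count=signal_count or len(signal_starts),
                     signal_depths=list(signal_depths),
                     signal_starts=list(signal_starts),
                     overlap_family=overlap_family, overlap_width=overlap_width)
    return Peak(chrom=chrom, start=start, end=end, strand=strand,
                read_idx=np.array([], dtype=int), features=f)


class TestReadFilters:
    @pytest.mark.parametrize("length,mm,expected", [
        (30, 3, True),   # boundary passes
        (29, 0, False),
        (100, 4, False),
        (100, 3, True),
    ])
    def test_improper_alignment(self, length, mm, expected):
        assert improper_alignment_filter(length, mm, CFG) is expected

    @pytest.mark.parametrize("overlap,a_frac,chimera", [
        (12, 0.6, True),   # long overlap, A-rich
        (8, 0.4, True),    # short overlap, A-poor
        (8, 0.6, False),
        (5, 0.4, False),
        (5, 0.6, False),
    ])
    def test_chimera_rule(self, overlap, a_frac, chimera):
        assert is_polyA_chimera(overlap, a_frac, CFG) is chimera

    def test_chimera_from_sequence(self):
        # flank span [0, 20), L1 span [8, 40): overlap 12, all T (A on L1 strand)
        seq = "C" * 8 + "T" * 12 + "G" * 20
        ok, evaluable = chimera_polyA_filter((8, 40), (0, 20), seq, CFG)
        assert evaluable and not ok

    def test_chimera_not_evaluable_passes(self):
        ok, evaluable = chimera_polyA_filter(None, (0, 20), "A" * 40, CFG)
        assert ok and not evaluable

    def test_misalignment(self):
        assert misalignment_filter("chr1", 100, "+", "chr1", 100, "+", CFG) == (True, True)
        assert misalignment_filter("chr1", 100, "+", "chr1", 101, "+", CFG) == (True, True)
        assert misalignment_filter("chr1", 100, "+", "chr2", 100, "+", CFG)[0] is False
        assert misalignment_filter("chr1", 100, "+", None, None, None, CFG) == (True, False)

    def test_local_sv_rejects_reference_derived_contig(self, genome, consensus):
        truth, _ = plan_truth(genome, n_local_sv=1, n_somatic=1, seed=9)
        df = generate_contigs(genome, truth, seed=9)
        sv = df[df.truth_id.str.contains("_sv")].iloc[0]
        som = df[df.truth_id.str.contains("_som")].iloc[0]
        assert not local_sv_filter(sv.sequence, sv.chrom, sv.start, sv.end,
                                   sv.strand, genome, CFG)
        assert local_sv_filter(som.sequence, som.chrom, som.start, som.end,
                               som.strand, genome, CFG)

    def test_local_sv_all_n_window_passes(self, genome):
        from tests.conftest import bare_genome
        g = bare_genome({"chr1": "N" * 20_000})
        assert local_sv_filter("ACGT" * 30, "chr1", 10_000, 10_100, "+", g, CFG)


class TestSignalMerging:
    def test_one_bp_shift_merges(self):
        starts, depths = merge_shifted_signals([100, 101], [2, 4], tol=1)
        assert starts == [101] and depths == [6]  # deeper start represents

    def test_distant_signals_kept(self):
        starts, depths = merge_shifted_signals([100, 150], [2, 2], tol=1)
        assert starts == [100, 150]

    def test_tie_prefers_smaller_coordinate(self):
        starts, _ = merge_shifted_signals([100, 101], [3, 3], tol=1)
        assert starts == [100]


class TestCategoryRules:
    def test_kr_all_criteria(self):
        p = make_peak(rpm=45, overlap_family="L1Hs", overlap_width=250)
        assert classify_kr(p, CFG) is None

    def test_kr_rpm_strict(self):
        p = make_peak(rpm=40, overlap_family="L1Hs", overlap_width=250)
        assert classify_kr(p, CFG) == "kr_rpm"

    def test_kr_chry_excluded(self):
        p = make_peak(chrom="chrY", rpm=45, overlap_family="L1Hs", overlap_width=250)
        assert classify_kr(p, CFG) == "chrY"

    def test_knr_inclusive_boundaries(self):
        p = make_peak(rpm=100, signal_starts=tuple(range(100, 160, 2)),
                      signal_depths=(5,) * 30)
        assert classify_knr(p, CFG) is None

    def test_knr_signal_count(self):
        p = make_peak(rpm=100, signal_starts=tuple(range(100, 158, 2)),
                      signal_depths=(5,) * 29)
        assert classify_knr(p, CFG) == "knr_signal_count"

    def test_knr_deep_signals(self):
        p = make_peak(rpm=100, signal_starts=tuple(range(100, 160, 2)),
                      signal_depths=(5, 5) + (2,) * 28)
        assert classify_knr(p, CFG) == "knr_deep_signals"

    def test_unk_boundary(self):
        p = make_peak(signal_starts=tuple(range(100, 120, 2)),
                      signal_depths=(5, 5, 5) + (1,) * 7)
        assert classify_unk(p, CFG) is None

    def test_unk_falls_through(self):
        p = make_peak(signal_starts=tuple(range(100, 118, 2)),
                      signal_depths=(5, 5, 5) + (1,) * 6)
        assert classify_unk(p, CFG) == "unk_signal_count"

    def test_somatic_needs_duplicate(self):
        p = make_peak(signal_starts=(100,), signal_depths=(3,))
        assert classify_somatic(p, 1, CFG) == ("somatic", None)
        p1 = make_peak(signal_starts=(100,), signal_depths=(1,))
        assert classify_somatic(p1, 1, CFG) == ("rejected", "no_pcr_duplicate")

    def test_shifted_signals_not_clonal(self):
        p = make_peak(signal_starts=(100, 101), signal_depths=(2, 4))
        assert classify_somatic(p, 1, CFG) == ("somatic", None)

    def test_clonal_definition(self):
        p = make_peak(signal_starts=(100, 150), signal_depths=(2, 2))
        assert classify_somatic(p, 1, CFG) == ("clonal_somatic", None)

    def test_observed_in_common_rejected(self):
        p = make_peak(signal_starts=(100, 150), signal_depths=(2, 2))
        assert classify_somatic(p, 2, CFG) == ("rejected", "observed_in_common")


class TestCascade:
    def test_partition_and_ledger(self, sim_cascade):
        res = sim_cascade["result"]
        led = res.ledger
        read_rejects = sum(led[k] for k in ("no_primer", "l1_identity",
                                            "diagnostic_motif", "improper_alignment",
                                            "misaligned", "chimera_polyA", "local_SV"))
        peaked = sum(p.n_reads for ps in res.peaks.values() for p in ps)
        assert read_rejects + peaked + led["unpeaked_reads"] == led["input_reads"]
        for call in res.calls:
            assert call.category in CATEGORIES
            assert (call.category == "rejected") == bool(call.rejection_reasons)

    def test_planted_sites_recovered(self, sim_cascade, sim_library):
        res = sim_cascade["result"]
        by_cat = {"KR": 0, "KNR": 0, "UNK": 0}
        for s in sim_library["truth"].germline_sites:
            by_cat[s.category] += 1
        assert res.ledger["calls_KR"] == by_cat["KR"]
        assert res.ledger["calls_KNR"] == by_cat["KNR"]
        assert res.ledger["calls_UNK"] == by_cat["UNK"]

    def test_artifacts_rejected_by_targeted_filter(self, sim_cascade):
        led = sim_cascade["result"].ledger
        assert led["chimera_polyA"] > 0
        assert led["misaligned"] > 0
        assert led["local_SV"] > 0

    def test_threshold_monotonicity(self, genome, sim_cascade, sim_library):
        """Lowering a category threshold never loses calls in that category."""
        relaxed = CFG.with_overrides(knr=CFG.knr.__class__(signal_min=5, rpm_min=10,
                                                          deep_signals_min=1,
                                                          deep_signal_depth=2))
        res = run_cascade(sim_cascade["parsed"], genome, sim_library["knr_db"],
                          relaxed, "S1", "I1")
        base = sim_cascade["result"].ledger
        assert res.ledger["calls_KNR"] >= base["calls_KNR"]


class TestUnassembled:
    def records(self, n_signals, chrom="chr1"):
        rows = []
        for i in range(n_signals):
            rows.append(dict(contig_id=f"u{i}", chrom=chrom, start=1000 + 5 * i,
                             end=1100 + 5 * i, strand="+", mapq=60, mismatches=0,
                             aligned_len=100, dup_group=f"u{i}",
                             start_position=1000 + 5 * i, sample="S1",
                             individual="I1", alt_chrom=chrom,
                             alt_start=1000 + 5 * i, alt_strand="+"))
        return pd.DataFrame(rows)

    def test_three_signal_candidate_is_low_confidence(self, genome):
        calls = classify_unassembled(self.records(6), genome, CFG)
        assert len(calls) == 1
        assert "low_confidence" in calls[0].flags

    def test_two_signals_dropped(self, genome):
        assert classify_unassembled(self.records(2), genome, CFG) == []

    def test_repeat_overlap_flagged(self, genome):
        rep = genome.repeats.iloc[0]
        df = self.records(4, chrom=rep.chrom)
        df["start"] = rep.start + np.arange(4) * 3
        df["end"] = df["start"] + 100
        df["start_position"] = df["start"]
        df["alt_chrom"], df["alt_start"] = df["chrom"], df["start"]
        calls = classify_unassembled(df, genome, CFG)
        assert calls and "repeat_overlap" in calls[0].flags
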