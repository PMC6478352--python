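"""Gene annotation, enrichment statistics and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hatseq.genomic_stats import (Transcript, annotate_region,
                                  canonical_transcripts, cluster_samples,
                                  fisher_or_test, orientation_binomial_test,
                                  region_binomial_test, region_bp_fractions)


def tx(gene="g", tx_id="t", chrom="c", strand="+", span=(1000, 9000),
       cds=(2500, 7500), exons=((1000, 3000), (5000, 9000))):
    return Transcript(gene=gene, tx_id=tx_id, chrom=chrom, strand=strand,
                      tx_start=span[0], tx_end=span[1], cds_start=cds[0],
                      cds_end=cds[1], exons=tuple(exons))


class TestCanonical:
    def test_longest_cds_wins(self):
        short = tx(tx_id="t1", cds=(2500, 2600))
        long_ = tx(tx_id="t2")
        assert canonical_transcripts([short, long_])["g"].tx_id == "t2"

    def test_tx_span_breaks_cds_ties(self):
        a = tx(tx_id="a", span=(1000, 9000))
        b = tx(tx_id="b", span=(500, 9500), exons=((1000, 3000), (5000, 9000)),
               cds=(2500, 7500))
        b = Transcript(gene="g", tx_id="b", chrom="c", strand="+", tx_start=500,
                       tx_end=9500, cds_start=2500, cds_end=7500,
                       exons=((1000, 3000), (5000, 9000)))
        assert canonical_transcripts([a, b])["g"].tx_id == "b"

    def test_length_class(self):
        assert tx().length_class == "short"
        long_tx = Transcript(gene="g", tx_id="t", chrom="c", strand="+",
                             tx_start=0, tx_end=150_000, cds_start=1000,
                             cds_end=120_000, exons=((500, 2000), (119_000, 121_000)))
        assert long_tx.length_class == "long"


class TestAnnotate:
    CANON = canonical_transcripts([tx()])

    def test_intron_orientation(self):
        assert annotate_region("c", 4000, "+", self.CANON) == ("intron", "g", "sense")
        assert annotate_region("c", 4000, "-", self.CANON) == ("intron", "g", "antisense")

    def test_intergenic(self):
        assert annotate_region("c", 500, "+", self.CANON) == ("intergenic", None, "NA")

    def test_utrs_respect_strand(self):
        assert annotate_region("c", 1500, "+", self.CANON)[0] == "5UTR"
        assert annotate_region("c", 8000, "+", self.CANON)[0] == "3UTR"
        minus = canonical_transcripts([tx(strand="-")])
        assert annotate_region("c", 1500, "-", minus)[0] == "3UTR"

    def test_cds_beats_utr_of_overlapping_gene(self):
        # two genes overlap; position is CDS for g2 but UTR-adjacent for g1
        g1 = tx(gene="g1", tx_id="a", span=(1000, 9000), cds=(8000, 8500),
                exons=((1000, 3000), (5000, 9000)))
        g2 = tx(gene="g2", tx_id="b")
        canon = canonical_transcripts([g1, g2])
        region, gene, _ = annotate_region("c", 2700, "+", canon)
        assert (region, gene) == ("CDS", "g2")

    def test_region_fractions_sum_to_one(self, genome):
        canon = canonical_transcripts(genome.gene_models)
        frac = region_bp_fractions(genome.contig_sizes, canon)
        assert sum(frac.values()) == pytest.approx(1.0)
        assert frac["intergenic"] > 0.5


class TestBinomialTests:
    def test_expected_count_gives_p_one(self):
        assert region_binomial_test(5, 10, 0.5)["p_value"] == pytest.approx(1.0)

    def test_exact_two_sided_value(self):
        # sum of binomial pmf over outcomes at most as probable as k=2
        res = region_binomial_test(2, 10, 0.5)
        assert res["p_value"] == pytest.approx(0.109375)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            region_binomial_test(1, 0, 0.5)
        with pytest.raises(ValueError):
            region_binomial_test(1, 10, 0.0)

    def test_orientation_balanced(self):
        assert orientation_binomial_test(50, 100)["p_value"] == pytest.approx(1.0)

    def test_orientation_extreme_closed_form(self):
        res = orientation_binomial_test(0, 10)
        assert res["p_value"] == pytest.approx(2 * 0.5**10)

    def test_label_swap_symmetry(self):
        a = orientation_binomial_test(30, 100)
        b = orientation_binomial_test(70, 100)
        assert a["p_value"] == pytest.approx(b["p_value"])
        assert a["proportion"] == pytest.approx(1 - b["proportion"])

    def test_type_i_error_calibrated(self):
        """Uniformly placed insertions reject at <= 6% at alpha = 0.05."""
        rng = np.random.default_rng(0)
        p0 = 0.37
        rejections = 0
        n_rep = 2000
        ks = rng.binomial(200, p0, size=n_rep)
        for k in ks:
            if region_binomial_test(int(k), 200, p0)["p_value"] < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.06


class TestFisher:
    def test_symmetric_table(self):
        res = fisher_or_test([[5, 5], [5, 5]])
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_extreme_table_vs_enumeration(self):
        res = fisher_or_test([[1, 9], [9, 1]])
        # brute-force: all tables with margins (10, 10 / 10, 10)
        n, r, c = 20, 10, 10
        probs = {a: sps.hypergeom.pmf(a, n, r, c) for a in range(11)}
        obs = probs[1]
        expected = sum(p for p in probs.values() if p <= obs * (1 + 1e-12))
        assert res["p_value"] == pytest.approx(expected)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            fisher_or_test([[0, 0], [3, 4]])

    def test_ci_covers_one_under_null(self):
        """Equal cohorts: the OR CI covers 1 in >= 93% of seeded runs."""
        rng = np.random.default_rng(1)
        cover = 0
        runs = 1000
        for _ in range(runs):
            a = rng.binomial(60, 0.3)
            b = rng.binomial(60, 0.3)
            try:
                res = fisher_or_test([[a, 60 - a], [b, 60 - b]])
            except ValueError:
                cover += 1  # degenerate margins carry no evidence against the null
                continue
            lo, hi = res["ci"]
            cover += lo <= 1.0 <= hi
        assert cover / runs >= 0.93


class TestClustering:
    def test_identical_profiles_pair_at_zero(self):
        presence = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 1, 0]],
                                index=["a1", "a2", "b1", "b2"],
                                columns=["l1", "l2", "l3"])
        res = cluster_samples(presence)
        assert res["partners"]["a1"] == "a2" and res["partners"]["b1"] == "b2"
        assert res["newick"].count("(") >= 2

    def test_empty_profile_flagged(self):
        presence = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"],
                                columns=["l1", "l2"])
        res = cluster_samples(presence)
        assert res["outliers"] == ["b"]

    def test_kr_loci_downweighted(self):
        # KR loci are shared by everyone and must not mask individual identity
        presence = pd.DataFrame([[1, 1, 1, 0], [1, 1, 1, 0],
                                 [1, 1, 0, 1], [1, 1, 0, 1]],
                                index=["a1", "a2", "b1", "b2"],
                                columns=["kr1", "kr2", "p1", "p2"])
        cats = {"kr1": "KR", "kr2": "KR", "p1": "KNR", "p2": "UNK"}
        res = cluster_samples(presence, locus_categories=cats)
        assert res["partners"]["a1"] == "a2" and res["partners"]["b2"] == "b1"

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame([[1]], index=["a"], columns=["l"]))
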