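"""EN-motif distances, control-site filtering, poly-A distributions."""

import re

import numpy as np
import pytest

from hatseq.config import EN_MOTIFS, MotifControlConfig
from hatseq.consensus import revcomp
from hatseq.tprt import (compare_distance_distributions, en_motif_distance,
                         polyA_length_distribution, random_control_sites)
from tests.conftest import bare_genome

CFG = MotifControlConfig()


def motif_free(rng, n):
    """Random sequence guaranteed free of all seven EN motifs."""
    seq = "".join(rng.choice(list("ACGT"), size=n))
    for m in EN_MOTIFS:
        seq = seq.replace(m, "ACGCGT")
    return seq


class TestMotifDistance:
    def test_motif_at_site_is_zero(self):
        rng = np.random.default_rng(0)
        seq = motif_free(rng, 5000) + "TTAAAA" + motif_free(rng, 5000)
        g = bare_genome({"c": seq})
        dist, flags = en_motif_distance("c", 5000, "+", g, CFG)
        assert dist == 0 and flags == []

    def test_downstream_offset(self):
        rng = np.random.default_rng(1)
        seq = motif_free(rng, 5000) + motif_free(rng, 37)[:37] + "TTGAAA" + motif_free(rng, 5000)
        seq = motif_free(rng, 5000) + "C" * 37 + "TTGAAA" + "G" * 5000
        g = bare_genome({"c": seq})
        dist, _ = en_motif_distance("c", 5000, "+", g, CFG)
        assert dist == 37

    def test_no_motif_in_window(self):
        rng = np.random.default_rng(2)
        g = bare_genome({"c": motif_free(rng, 10_000)})
        dist, flags = en_motif_distance("c", 5000, "+", g, CFG)
        assert dist is None and "no_motif" in flags

    def test_window_truncated_flag(self):
        g = bare_genome({"c": "TTAAAA" + "G" * 10_000})
        dist, flags = en_motif_distance("c", 100, "+", g, CFG)
        assert "window_truncated" in flags
        assert dist == -100

    def test_matches_regex_oracle(self):
        rng = np.random.default_rng(3)
        pattern = re.compile("|".join(EN_MOTIFS))
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=1200))
            g = bare_genome({"c": seq})
            pos = int(rng.integers(100, 1100))
            dist, flags = en_motif_distance("c", pos, "+", g, CFG)
            hits = [m.start() - pos for m in pattern.finditer(seq)]
            # overlapping occurrences: also scan shifted starts
            hits = [s - pos for s in range(len(seq) - 5)
                    if seq[s:s + 6] in EN_MOTIFS]
            if not hits:
                assert dist is None
            else:
                assert dist in hits
                assert abs(dist) == min(abs(h) for h in hits)

    def test_strand_mirror_symmetry(self):
        """A minus-strand site on the genome equals a plus-strand site on
        the reverse-complemented genome."""
        rng = np.random.default_rng(4)
        seq = motif_free(rng, 4000) + "TTAAGA" + motif_free(rng, 4000)
        g = bare_genome({"c": seq})
        g_rc = bare_genome({"c": revcomp(seq)})
        pos = 3000
        d1, _ = en_motif_distance("c", pos, "-", g, CFG)
        d2, _ = en_motif_distance("c", len(seq) - pos, "+", g_rc, CFG)
        assert d1 == d2


class TestControlSites:
    def test_fully_mappable_keeps_all(self):
        rng = np.random.default_rng(5)
        g = bare_genome({"c": motif_free(rng, 30_000)})
        cfg = MotifControlConfig(n_random=200)
        sites = random_control_sites(g, cfg=cfg, seed=1)
        assert len(sites) == 200

    def test_low_mappability_excluded(self):
        rng = np.random.default_rng(6)
        g = bare_genome({"c": motif_free(rng, 30_000)})
        g.mappability["c"][:] = 1.0
        g.mappability["c"][10_000:22_000] = 0.1  # windows there are >20% low-map
        cfg = MotifControlConfig(n_random=300)
        sites = random_control_sites(g, cfg=cfg, seed=2)
        assert all(not (12_000 < pos < 20_000) for _, pos, _ in sites)
        assert len(sites) < 300

    def test_n_rich_windows_excluded(self):
        g = bare_genome({"c": "N" * 30_000})
        cfg = MotifControlConfig(n_random=50)
        assert random_control_sites(g, cfg=cfg, seed=3) == []

    def test_boundary_rules_exact(self):
        """Exactly the windows violating a printed rule are removed."""
        cfg = MotifControlConfig(n_random=1, window_bp=100)
        rng = np.random.default_rng(7)
        base = motif_free(rng, 400)
        # 25% low-mappability in the window -> excluded
        g = bare_genome({"c": base})
        g.mappability["c"][:] = 1.0
        g.mappability["c"][150:200] = 0.1  # 50/200 = 25% > 20%
        from hatseq.tprt import _window_ok
        assert not _window_ok(g, g.mappability, "c", 200, cfg)
        g.mappability["c"][:] = 1.0
        g.mappability["c"][160:200] = 0.1  # exactly 20% is allowed
        assert _window_ok(g, g.mappability, "c", 200, cfg)
        # 95% N -> excluded; 90% N allowed
        seq95 = "N" * 190 + base[:10]
        g2 = bare_genome({"c": seq95 + base})
        assert not _window_ok(g2, None, "c", 100, cfg)
        seq90 = "N" * 180 + base[:20]
        g3 = bare_genome({"c": seq90 + base})
        assert _window_ok(g3, None, "c", 100, cfg)


class TestDistanceComparison:
    def test_identical_samples_p_one(self):
        res = compare_distance_distributions([5, 5, 5], [5, 5, 5])
        assert res["p_value"] == 1.0

    def test_small_sample_exact(self):
        # exact enumeration over all C(6,3) splits gives p = 0.1
        res = compare_distance_distributions([1, 2, 3], [10, 11, 12])
        assert res["p_value"] == pytest.approx(0.1)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            compare_distance_distributions([], [1.0])

    def test_en_biased_sites_vs_uniform_controls(self):
        """Sites planted near EN motifs separate from uniform controls at
        alpha = 1e-6."""
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=200_000))
        g = bare_genome({"c": seq})
        motif_hits = [s for s in range(2500, len(seq) - 2500)
                      if seq[s:s + 6] in EN_MOTIFS]
        biased = rng.choice(motif_hits, size=250, replace=False)
        biased_d = [en_motif_distance("c", int(p) + int(rng.integers(0, 4)), "+", g)[0]
                    for p in biased]
        controls = rng.integers(2500, len(seq) - 2500, size=250)
        control_d = [en_motif_distance("c", int(p), "+", g)[0] for p in controls]
        res = compare_distance_distributions(
            [d for d in biased_d if d is not None],
            [d for d in control_d if d is not None])
        assert res["p_value"] < 1e-6


class TestPolyADistribution:
    def test_constant_lengths(self):
        res = polyA_length_distribution([25] * 40)
        assert res["mode"] == 25 and not res["bimodal"]

    def test_simulator_mode_recovery(self):
        # parameter recovery: many site-level tails drawn from the
        # generator's tail model have mode 25 (+/- bin width)
        from hatseq.simdata import LibraryParams, _tail_len
        rng = np.random.default_rng(9)
        tails = [_tail_len(rng, LibraryParams()) for _ in range(5000)]
        res = polyA_length_distribution(tails)
        assert abs(res["mode"] - 25) <= 1

    def test_parsed_tails_match_planted(self, sim_cascade, sim_library):
        # every genuine read's scored poly-T length equals its site's tail
        parsed = sim_cascade["parsed"]
        genuine = parsed[~parsed["truth_id"].str.contains("_chi|_sv|_mis")]
        tail_by_read = genuine.groupby("truth_id")["polyT_len"].nunique()
        assert (tail_by_read == 1).all()  # one tail length per planted site

    def test_bimodal_fixture(self):
        res = polyA_length_distribution([10] * 30 + [40] * 29)
        assert res["bimodal"]

    def test_empty(self):
        assert polyA_length_distribution([])["n"] == 0
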