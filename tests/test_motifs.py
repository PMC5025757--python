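"""PWM building, exact-threshold scanning, dyads and flank enrichment."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gbsflank import (
    CGT_CORE,
    RegulatoryFixtureSpec,
    build_pwm,
    dyad_enrichment,
    flank_enrichment,
    make_regulatory_fixture,
    parse_tab_matrix,
    parse_transfac,
    peak_height_by_flank,
    scan_sequences,
    score_threshold,
    simulation_duplex,
)
from gbsflank._seq import revcomp
from gbsflank.motifs import background_from_seqs, score_distribution

AT_DUPLEX = "CACCAAGAACATTTTGTACGTCTC"
GC_DUPLEX = "CACCGAGAACATTTTGTACGCCTC"


class TestPwm:
    def test_single_site_no_pseudocount_ic_two_bits(self):
        pwm = build_pwm(["ACGTA"], pseudocount=0.0)
        assert np.allclose(pwm.information_content, 2.0)

    def test_uniform_column_zero_bits(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        assert np.allclose(pwm.information_content, 0.0)

    def test_ic_matches_direct_formula(self, rng):
        sites = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(50)]
        pwm = build_pwm(sites, pseudocount=1.0)
        f = pwm.frequencies
        expected = np.array([
            sum(f[b, j] * math.log2(f[b, j] / 0.25) for b in range(4) if f[b, j] > 0)
            for j in range(8)
        ])
        assert np.allclose(pwm.information_content, expected, atol=1e-12)

    def test_frequency_columns_sum_to_one(self, cgt_pwm):
        assert np.allclose(cgt_pwm.frequencies.sum(axis=0), 1.0)

    def test_transfac_and_tab_parsers_agree(self):
        counts = np.array([[5, 0], [1, 2], [0, 8], [4, 0]])
        transfac = "ID test\nP0 A C G T\n01 5 1 0 4\n02 0 2 8 0\n//\n"
        tab = "A\t5\t0\nC\t1\t2\nG\t0\t8\nT\t4\t0\n"
        p1 = parse_transfac(transfac)
        p2 = parse_tab_matrix(tab)
        assert np.array_equal(p1.counts, counts)
        assert np.array_equal(p1.counts, p2.counts)


class TestScoreThreshold:
    def test_distribution_sums_to_one(self, cgt_pwm):
        _, probs = score_distribution(cgt_pwm, resolution=0.01)
        assert np.isclose(probs.sum(), 1.0, atol=1e-9)

    def test_pvalue_one_gives_min_score(self, cgt_pwm):
        cut = score_threshold(cgt_pwm, 1.0, resolution=0.001)
        assert np.isclose(cut, cgt_pwm.min_score(), atol=0.01)

    def test_width3_distribution_matches_exhaustive_enumeration(self, rng):
        pwm = build_pwm(["".join(rng.choice(list("ACGT"), 3)) for _ in range(12)],
                        pseudocount=0.7)
        res = 1e-3
        bins = np.round(pwm.log_odds / res).astype(int)
        word_mass = {}
        for w in itertools.product(range(4), repeat=3):
            s = sum(bins[b, j] for j, b in enumerate(w))
            word_mass[s] = word_mass.get(s, 0.0) + 1 / 64
        scores, probs = score_distribution(pwm, resolution=res)
        assert set(word_mass) == {round(s / res) for s in scores}
        oracle = np.array([word_mass[round(s / res)] for s in scores])
        np.testing.assert_allclose(probs, oracle, atol=1e-12)

    def test_cutoff_monotone_in_pvalue(self, cgt_pwm):
        cuts = [score_threshold(cgt_pwm, p) for p in (1.0, 0.1, 1e-2, 1e-4)]
        assert all(a <= b for a, b in zip(cuts, cuts[1:]))

    def test_unachievable_pvalue_warns(self, cgt_pwm):
        with pytest.warns(UserWarning, match="minimal achievable"):
            cut = score_threshold(cgt_pwm, 1e-12)
        assert cut > cgt_pwm.max_score()


class TestScan:
    def test_at_duplex_one_ww_match(self, cgt_pwm, cgt_cutoff):
        assert simulation_duplex("A", "T") == AT_DUPLEX
        hits = scan_sequences({"cgt": AT_DUPLEX}, cgt_pwm, cgt_cutoff)
        plus = hits[hits.strand == "+"]
        assert len(plus) == 1
        row = plus.iloc[0]
        assert (row.offset, row.flank5, row.flank3, row.flank_class) == (5, "A", "T", "WW")

    def test_gc_duplex_same_offset_ss(self, cgt_pwm, cgt_cutoff):
        assert simulation_duplex("G", "C") == GC_DUPLEX
        hits = scan_sequences({"cgt": GC_DUPLEX}, cgt_pwm, cgt_cutoff)
        plus = hits[hits.strand == "+"]
        assert len(plus) == 1
        row = plus.iloc[0]
        assert (row.offset, row.flank_class) == (5, "SS")

    def test_reverse_complement_symmetry(self, cgt_pwm, cgt_cutoff, rng):
        seq = "".join(rng.choice(list("ACGT"), 50)) + AT_DUPLEX + \
              "".join(rng.choice(list("ACGT"), 30))
        L = len(seq)
        fwd = scan_sequences({"s": seq}, cgt_pwm, cgt_cutoff)
        rev = scan_sequences({"s": revcomp(seq)}, cgt_pwm, cgt_cutoff)
        w = cgt_pwm.width
        mapped = {(L - w - o, {"+": "-", "-": "+"}[s], round(sc, 9))
                  for o, s, sc in zip(rev.offset, rev.strand, rev.score)}
        direct = {(o, s, round(sc, 9)) for o, s, sc in zip(fwd.offset, fwd.strand, fwd.score)}
        assert mapped == direct

    def test_edge_window_flagged(self, cgt_pwm):
        # match flush at the sequence start: no room for the -8 flank
        hits = scan_sequences({"s": CGT_CORE + "TTTT"}, cgt_pwm, cutoff=15.0)
        plus = hits[(hits.strand == "+") & (hits.offset == 0)]
        assert len(plus) == 1 and plus.iloc[0].flank_class == "edge"

    def test_n_windows_never_match(self, cgt_pwm):
        seq = CGT_CORE.replace("A", "N", 1) + "ACGTACGT"
        hits = scan_sequences({"s": seq}, cgt_pwm, cutoff=-100.0)
        assert np.isfinite(hits.score).all()
        # the N sits inside every window starting at offset 0 on either strand
        assert 0 not in set(hits.offset[hits.strand == "+"])


class TestDyads:
    def test_tiny_input_counts_match_exhaustive(self):
        seqs = {"a": "ACGTACGTACGT", "b": "TTTTACGTAAAA"}
        df = dyad_enrichment(seqs, monad_len=3, max_spacing=2, background=[0.25] * 4)
        strands = [s for seq in seqs.values() for s in (seq, revcomp(seq))]
        for _, row in df.sample(80, random_state=0).iterrows():
            s = int(row.spacing)
            expected = sum(
                1
                for seq in strands
                for i in range(len(seq) - 6 - s + 1)
                if seq[i:i + 3] == row.monad5 and seq[i + 3 + s:i + 6 + s] == row.monad3
            )
            assert row.observed == expected
        # ACG.ACG with spacing 1 occurs twice on each strand of sequence "a"
        planted = df[(df.monad5 == "ACG") & (df.monad3 == "ACG") & (df.spacing == 1)]
        assert planted.iloc[0].observed == 4

    def test_absent_dyad_p_one_sig_nonpositive(self):
        seqs = {"a": "A" * 30}
        df = dyad_enrichment(seqs, monad_len=3, max_spacing=1, background=[0.25] * 4)
        absent = df[(df.monad5 == "CCC") & (df.monad3 == "GGG") & (df.spacing == 0)]
        assert absent.iloc[0].p_value == 1.0
        assert absent.iloc[0].sig <= 0

    def test_binomial_tail_equals_summation_oracle(self):
        seqs = {"a": "ACGTACGTACGTACGTACGTACGTACG"}
        df = dyad_enrichment(seqs, monad_len=3, max_spacing=0, background=[0.25] * 4)
        n = 2 * (len(seqs["a"]) - 6 + 1)
        p_word = (0.25**3) ** 2
        for _, row in df.head(50).iterrows():
            k = int(row.observed)
            oracle = sum(
                math.comb(n, j) * p_word**j * (1 - p_word) ** (n - j)
                for j in range(k, n + 1)
            )
            assert row.p_value == pytest.approx(oracle, rel=1e-9, abs=1e-300)

    def test_planted_dyad_ranks_first(self, rng):
        seqs = {}
        for i in range(20):
            bg = rng.choice(list("ACGT"), 40)
            off = rng.integers(0, 40 - 9)
            insert = "AGA" + "".join(rng.choice(list("ACGT"), 3)) + "TGT"
            s = "".join(bg[:off]) + insert + "".join(bg[off + 9:])
            seqs[f"s{i}"] = s
        df = dyad_enrichment(seqs, monad_len=3, max_spacing=6)
        top = df.iloc[0]
        # the planted dyad (or its reverse complement, counted identically)
        assert {(top.monad5, top.monad3, top.spacing),
                (revcomp(top.monad3), revcomp(top.monad5), top.spacing)} & \
               {("AGA", "TGT", 3), ("ACA", "TCT", 3)}

    def test_zero_probability_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            dyad_enrichment({"a": "ACGT" * 10}, max_spacing=0,
                            background=[0.5, 0.5, 0.0, 0.0])

    def test_background_from_seqs_strand_symmetric(self):
        bg = background_from_seqs({"a": "AAAACCC"})
        assert bg[0] == bg[3] and bg[1] == bg[2]
        assert np.isclose(bg.sum(), 1.0)


class TestFlankEnrichment:
    def test_identical_sets_delta_zero(self, cgt_pwm, cgt_cutoff, rng):
        seqs = {}
        for i in range(20):
            pad = "".join(rng.choice(list("ACGT"), 20))
            flank = ("A", "T") if i % 2 else ("G", "C")
            seqs[f"p{i}"] = pad + flank[0] + CGT_CORE + flank[1] + pad
        res = flank_enrichment(seqs, dict(seqs), cgt_pwm, cgt_cutoff,
                               n_perm=300, seed=5)
        assert res.delta == 0.0
        assert res.perm_p > 0.25  # exchangeable null

    def test_label_swap_negates_delta(self, small_fixture, cgt_pwm, cgt_cutoff):
        s = small_fixture.peak_sequences("strong")
        w = small_fixture.peak_sequences("weak")
        a = flank_enrichment(s, w, cgt_pwm, cgt_cutoff, n_perm=120, seed=1)
        b = flank_enrichment(w, s, cgt_pwm, cgt_cutoff, n_perm=120, seed=1)
        assert a.delta == pytest.approx(-b.delta, abs=1e-12)

    def test_planted_flank_bias_recovered(self, cgt_pwm, cgt_cutoff):
        spec = RegulatoryFixtureSpec(
            seed=7, n_genes=600, n_significant=300, chrom_length=10_000_000,
            n_peaks_per_group=200, peak_len=80,
            strong_flank_bias=0.9, weak_flank_bias=0.9,
        )
        fx = make_regulatory_fixture(spec)
        res = flank_enrichment(
            fx.peak_sequences("strong"), fx.peak_sequences("weak"),
            cgt_pwm, cgt_cutoff, n_perm=500, seed=7,
        )
        assert res.delta > 0
        assert res.perm_p < 0.05

    def test_super_uniform_under_null(self, cgt_pwm, cgt_cutoff):
        rng = np.random.default_rng(99)
        n_reps, alpha_hits = 200, 0
        for rep in range(n_reps):
            groups = []
            for g in range(2):
                seqs = {}
                for i in range(20):
                    pad5 = "".join(rng.choice(list("ACGT"), 12))
                    pad3 = "".join(rng.choice(list("ACGT"), 12))
                    flank = ("A", "T") if rng.random() < 0.5 else ("G", "C")
                    seqs[f"g{g}p{i}"] = pad5 + flank[0] + CGT_CORE + flank[1] + pad3
                groups.append(seqs)
            res = flank_enrichment(groups[0], groups[1], cgt_pwm, cgt_cutoff,
                                   n_perm=119, seed=rep)
            alpha_hits += res.perm_p < 0.05
        assert alpha_hits / n_reps <= 0.08


class TestPeakHeight:
    @staticmethod
    def _peaks(rng, n, flank_pool, heights):
        seqs, rows = {}, []
        for i, h in enumerate(heights):
            pad5 = "".join(rng.choice(list("ACGT"), 12))
            pad3 = "".join(rng.choice(list("ACGT"), 12))
            f5, f3 = rng.choice(list(flank_pool), 2)
            pid = f"{flank_pool}{i}"
            seqs[pid] = pad5 + f5 + CGT_CORE + f3 + pad3
            rows.append(("chr1", 0, 42, pid, h, "."))
        return seqs, rows

    def test_equal_heights_equal_medians(self, cgt_pwm, cgt_cutoff, rng):
        sw, rw = self._peaks(rng, 5, "AT", [7.0] * 5)
        ss, rs = self._peaks(rng, 5, "GC", [7.0] * 5)
        peaks = pd.DataFrame(rw + rs, columns=["chrom", "start", "end", "name", "score", "strand"])
        out = peak_height_by_flank(peaks, {**sw, **ss}, cgt_pwm, cgt_cutoff)
        med = dict(zip(out.flank_class, out.median_height))
        assert med["WW"] == med["SS"] == 7.0

    def test_single_ww_peak_median_is_its_height(self, cgt_pwm, cgt_cutoff, rng):
        sw, rw = self._peaks(rng, 1, "AT", [5.0])
        peaks = pd.DataFrame(rw, columns=["chrom", "start", "end", "name", "score", "strand"])
        out = peak_height_by_flank(peaks, sw, cgt_pwm, cgt_cutoff)
        med = dict(zip(out.flank_class, out.median_height))
        n = dict(zip(out.flank_class, out.n_peaks))
        assert med["WW"] == 5.0 and n["WW"] == 1
        assert np.isnan(med["SS"]) and n["SS"] == 0

    def test_identical_height_distributions_ratio_near_one(self, cgt_pwm, cgt_cutoff):
        rng = np.random.default_rng(42)
        heights = rng.normal(100, 20, size=1000).clip(1)
        sw, rw = self._peaks(rng, 500, "AT", heights[:500])
        ss, rs = self._peaks(rng, 500, "GC", heights[500:])
        peaks = pd.DataFrame(rw + rs, columns=["chrom", "start", "end", "name", "score", "strand"])
        out = peak_height_by_flank(peaks, {**sw, **ss}, cgt_pwm, cgt_cutoff)
        med = dict(zip(out.flank_class, out.median_height))
        assert abs(med["WW"] / med["SS"] - 1) < 0.10
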