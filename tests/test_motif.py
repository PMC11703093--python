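"""PWM scoring, scanning, enrichment, GC-matched controls, erosion test."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import recfin as rf
from recfin import motif as mot
from recfin import synthetic as syn


def sharp_pwm(consensus, major=0.88):
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(consensus), 4), (1 - major) / 3)
    for j, b in enumerate(consensus):
        probs[j, idx[b]] = major
    return mot.Pwm(probs, name="test")


def enumeration_tail(pwm, t_int):
    """Exact background tail P(int score >= t) by enumerating all words."""
    ints = pwm.int_scores()
    w = pwm.width
    total = 0.0
    for word in product(range(4), repeat=w):
        s = sum(int(ints[j, a]) for j, a in enumerate(word))
        if s >= t_int:
            total += float(np.prod([pwm.background[a] for a in word]))
    return total


class TestScoreThreshold:
    def test_dp_tail_matches_enumeration(self, rng):
        for _ in range(10):
            w = int(rng.integers(2, 5))
            pwm = mot.Pwm(rng.dirichlet([0.5] * 4, size=w),
                          rng.dirichlet([5.0] * 4))
            grid, probs = mot.score_distribution(pwm)
            dp_tail = np.cumsum(probs[::-1])[::-1]
            for t in (grid[0], grid[len(grid) // 3], grid[-3]):
                assert dp_tail[grid == t][0] == pytest.approx(
                    enumeration_tail(pwm, t), abs=1e-12)

    def test_pcut_one_gives_minimum_score(self):
        pwm = sharp_pwm("ACGT")
        grid, _ = mot.score_distribution(pwm)
        thr = mot.score_threshold(pwm, p_cut=1.0)
        assert thr == pytest.approx(grid[0] * mot.BIN_BITS)

    def test_background_pwm_scores_zero(self):
        pwm = mot.Pwm(np.full((6, 4), 0.25))
        assert pwm.log_odds() == pytest.approx(0.0)
        with pytest.warns(UserWarning, match="resolution"):
            thr = mot.score_threshold(pwm, p_cut=0.5)
        assert thr == pytest.approx(0.0, abs=1e-9)

    def test_pcut_below_resolution_warns_max(self):
        pwm = sharp_pwm("ACG")  # 64 words: min tail 1/64 >> 1e-7
        with pytest.warns(UserWarning, match="resolution"):
            thr = mot.score_threshold(pwm, p_cut=1e-7)
        grid, _ = mot.score_distribution(pwm)
        assert thr == pytest.approx(grid[-1] * mot.BIN_BITS)

    def test_invalid_pcut(self):
        with pytest.raises(ValueError):
            mot.score_threshold(sharp_pwm("ACGT"), p_cut=0.0)


class TestScan:
    def test_planted_consensus_found_exactly(self, rng):
        pwm = sharp_pwm("ACGTACGTACGT")
        thr = mot.score_threshold(pwm, 1e-7)
        base = syn.random_genome(50_000, 0.5, rng)
        offsets = [1000, 20_000, 40_000]
        seq = list(base)
        for off in offsets:
            seq[off:off + 12] = "ACGTACGTACGT"
        hits = mot.scan("".join(seq), pwm, thr)
        plus = hits[hits["strand"] == "+"]["pos"].tolist()
        assert set(offsets) <= set(plus)

    def test_strand_symmetry(self, rng):
        pwm = mot.Pwm(rng.dirichlet([0.5] * 4, size=8))
        thr = mot.score_threshold(pwm, 1e-3)
        seq = syn.random_genome(20_000, 0.45, rng)
        rc = str.maketrans("ACGT", "TGCA")
        rev = seq.translate(rc)[::-1]
        fwd_hits = mot.scan(seq, pwm, thr)
        rev_hits = mot.scan(rev, pwm, thr)
        L, W = len(seq), pwm.width
        mapped = sorted((L - W - p, {"+": "-", "-": "+"}[s])
                        for p, s in zip(rev_hits["pos"], rev_hits["strand"]))
        assert mapped == sorted(zip(fwd_hits["pos"], fwd_hits["strand"]))

    def test_n_windows_skipped(self):
        pwm = sharp_pwm("ACGT")
        thr = mot.score_threshold(pwm, 0.003)  # keeps only the consensus
        hits = mot.scan("ACGT" + "N" * 4 + "ACGT", pwm, thr)
        assert set(hits["pos"]) <= {0, 8}

    def test_hit_rate_matches_pvalue(self, rng):
        pwm = mot.Pwm(rng.dirichlet([0.8] * 4, size=10))
        p_cut = 1e-4
        thr = mot.score_threshold(pwm, p_cut)
        tail = mot.tail_probability(pwm, thr)
        n_hits = 0
        n_windows = 0
        for _ in range(5):
            seq = syn.random_genome(100_000, 0.5, rng)
            n_hits += len(mot.scan(seq, pwm, thr))
            n_windows += 2 * (len(seq) - pwm.width + 1)
        expected = n_windows * tail
        assert abs(n_hits - expected) < 4 * np.sqrt(expected)


class TestCountInBlocks:
    def test_empty_blocks_zero(self, rng):
        pwm = sharp_pwm("ACGTACGT")
        thr = mot.score_threshold(pwm, 1e-4)
        seq = syn.random_genome(10_000, 0.5, rng)
        assert mot.count_hits(seq, pwm, thr,
                              pd.DataFrame(columns=["chrom", "start", "end"])) == 0

    def test_full_blocks_equal_plain_scan(self, rng):
        pwm = mot.Pwm(rng.dirichlet([0.6] * 4, size=8))
        thr = mot.score_threshold(pwm, 1e-3)
        seq = syn.random_genome(30_000, 0.5, rng)
        full = pd.DataFrame({"chrom": ["chr"], "start": [0], "end": [len(seq)]})
        assert mot.count_hits(seq, pwm, thr, full) == mot.count_hits(seq, pwm, thr)

    def test_half_coverage_half_hits(self, rng):
        pwm = mot.Pwm(rng.dirichlet([0.6] * 4, size=8))
        thr = mot.score_threshold(pwm, 1e-3)
        seq = syn.random_genome(200_000, 0.5, rng)
        half = pd.DataFrame({"chrom": ["chr"], "start": [0], "end": [100_000]})
        n_half = mot.count_hits(seq, pwm, thr, half)
        n_full = mot.count_hits(seq, pwm, thr)
        assert n_half == pytest.approx(n_full / 2, abs=4 * np.sqrt(n_full / 2))


class TestErosion:
    def test_printed_lineage_means_reproduce_reduction(self):
        ma, mb, pct = mot.erosion_statistics([3329], [3230])
        assert round(pct, 2) == 2.97

    def test_identical_lineages_null(self, rng):
        pwm = sharp_pwm("ACGTTGCAACGT")
        base = syn.random_genome(100_000, 0.42, rng)
        er = syn.gen_eroded_genomes(base, pwm, 300, (3, 3), 0.0,
                                    neutral_rate=0.0, seed=rng)
        thr = mot.score_threshold(pwm, 1e-7)
        ca = [mot.count_hits(s, pwm, thr) for s in er.genomes_a.values()]
        cb = [mot.count_hits(s, pwm, thr) for s in er.genomes_b.values()]
        res = mot.erosion_test(ca, cb, pwm, er.genomes_a, er.genomes_b,
                               er.blocks, n_perm=19, seed=0)
        assert res.percent_reduction == 0.0
        assert res.p_value == 1.0

    def test_full_erosion_removes_planted_hits(self, rng):
        pwm = sharp_pwm("ACGTTGCAACGT")
        base = syn.random_genome(100_000, 0.42, rng)
        er = syn.gen_eroded_genomes(base, pwm, 300, (2, 2), 1.0,
                                    neutral_rate=0.0, seed=rng)
        thr = mot.score_threshold(pwm, 1e-7)
        cb = [mot.count_hits(s, pwm, thr) for s in er.genomes_b.values()]
        assert max(cb) == 0

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            mot.erosion_statistics([0, 0], [1, 2])

    def test_seed_reproducible_null(self, rng):
        pwm = sharp_pwm("ACGTTGCA")
        base = syn.random_genome(30_000, 0.42, np.random.default_rng(5))
        er = syn.gen_eroded_genomes(base, pwm, 50, (2, 2), 0.5,
                                    seed=np.random.default_rng(5))
        thr = mot.score_threshold(pwm, 1e-5)
        ca = [mot.count_hits(s, pwm, thr) for s in er.genomes_a.values()]
        cb = [mot.count_hits(s, pwm, thr) for s in er.genomes_b.values()]
        kwargs = dict(p_cut=1e-4, n_perm=10)
        r1 = mot.erosion_test(ca, cb, pwm, er.genomes_a, er.genomes_b,
                              er.blocks, seed=3, **kwargs)
        r2 = mot.erosion_test(ca, cb, pwm, er.genomes_a, er.genomes_b,
                              er.blocks, seed=3, **kwargs)
        np.testing.assert_array_equal(r1.null, r2.null)


class TestEnrichment:
    def test_equal_fractions_not_retained(self):
        res = rf.enrichment_at_hotspots([True] * 5 + [False] * 5,
                                        [True] * 50 + [False] * 50)
        assert res.fold == pytest.approx(1.0)
        assert not res.retained

    def test_two_fold_retained(self):
        hot = [True] * 10 + [False] * 90
        ctrl = [True] * 50 + [False] * 950
        res = rf.enrichment_at_hotspots(hot, ctrl)
        assert res.fold == pytest.approx(2.0)
        assert res.retained  # 10% of hotspots >= 5%

    def test_planted_motif_enrichment_significant(self, rng):
        pwm = sharp_pwm("ACGTTGCAACGT")
        thr = mot.score_threshold(pwm, 1e-7)
        hot = ["".join(s) for s in
               (list(syn.random_genome(2000, 0.42, rng)) for _ in range(40))]
        hot = [h[:1000] + "ACGTTGCAACGT" + h[1012:] if i < 30 else h
               for i, h in enumerate(hot)]
        ctrl = [syn.random_genome(2000, 0.42, rng) for _ in range(200)]
        hp = [len(mot.scan(h, pwm, thr)) > 0 for h in hot]
        cp = [len(mot.scan(c, pwm, thr)) > 0 for c in ctrl]
        res = rf.enrichment_at_hotspots(hp, cp)
        assert res.retained
        assert res.p_value < 0.05


class TestGcMatchedControls:
    def test_per_bin_quota_matches_hotspots(self, rng):
        genome = {"chr1": syn.random_genome(500_000, 0.45, rng)}
        allowed = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                "end": [500_000]})
        hs_gc = np.array([0.43, 0.44, 0.45, 0.46, 0.47])
        ctrl = rf.sample_gc_matched_controls(genome, hs_gc, allowed,
                                             width=2000, n_per_target=4,
                                             seed=1)
        assert len(ctrl) == 20
        bins_h = np.floor(hs_gc / 0.025).astype(int)
        bins_c = np.floor(ctrl["gc"].to_numpy() / 0.025).astype(int)
        for b in set(bins_h):
            assert (bins_c == b).sum() == 4 * (bins_h == b).sum()

    def test_single_bin_controls_in_that_bin(self, rng):
        genome = {"chr1": syn.random_genome(300_000, 0.45, rng)}
        allowed = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                "end": [300_000]})
        ctrl = rf.sample_gc_matched_controls(genome, np.array([0.45, 0.46]),
                                             allowed, width=2000,
                                             n_per_target=3, seed=2)
        assert (np.floor(ctrl["gc"] / 0.025) == 18).all()


class TestCentrality:
    def test_zero_hits_p_one(self):
        p, _, _ = rf.centrality_test(np.array([]), 400, 2000)
        assert p == 1.0

    def test_all_central_hits_tiny_p(self, rng):
        pos = rng.integers(900, 1100, size=40)
        p, _, _ = rf.centrality_test(pos, 400, 2000)
        assert p < 1e-6

    def test_uniform_hits_calibrated(self, rng):
        ps = []
        for _ in range(200):
            pos = rng.integers(0, 2000, size=50)
            p, _, _ = rf.centrality_test(pos, 400, 2000)
            ps.append(p)
        assert 0.01 <= np.mean(np.array(ps) <= 0.05) <= 0.12

    def test_total_must_exceed_center(self):
        with pytest.raises(ValueError):
            rf.centrality_test(np.array([1]), 2000, 2000)
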