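"""CGI prediction and feature-relative enrichment."""

import numpy as np
import pandas as pd
import pytest

import recfin as rf
from recfin import intervals as iv
from recfin.features import CgiParams, GenomeAnnotation

from conftest import make_map, uniform_map


def window_oe(seq):
    """Direct obs/exp CpG for one full window (oracle for the formula)."""
    nc = seq.count("C")
    ng = seq.count("G")
    ncpg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    return 0.0 if nc * ng == 0 else ncpg * len(seq) / (nc * ng)


class TestPredictCgis:
    def test_poly_a_no_island(self):
        assert len(rf.predict_cgis("A" * 10_000)) == 0

    def test_cg_repeat_island(self):
        seq = "AT" * 2000 + "CG" * 300 + "TA" * 2000
        cgis = rf.predict_cgis(seq)
        assert len(cgis) == 1
        s, e = cgis.iloc[0][["start", "end"]]
        assert e - s >= 250
        # the repeat itself lies inside the island
        assert s <= 4000 and e >= 4600

    def test_zero_c_or_g_is_guarded(self):
        # all-G window has zero C: obs/exp must be 0, not an error
        assert window_oe("G" * 500) == 0.0
        assert len(rf.predict_cgis("G" * 2000)) == 0

    def test_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter than window"):
            out = rf.predict_cgis("ACGT" * 50)
        assert len(out) == 0

    def test_islands_disjoint_and_audited(self, rng):
        # noisy sequence with two separated CpG-rich patches
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, p=[0.4, 0.1, 0.1, 0.4], size=20_000))
        seq = seq[:5000] + "CG" * 250 + seq[5500:12_000] + "CG" * 250 + seq[12_500:]
        cgis = rf.predict_cgis(seq)
        assert len(cgis) >= 2
        iv.check_sorted_disjoint(cgis)
        for _, row in cgis.iterrows():
            assert row["end"] - row["start"] >= 250

    def test_min_gc_threshold_respected(self):
        seq = "AT" * 2000 + "CG" * 300 + "TA" * 2000
        none = rf.predict_cgis(seq, CgiParams(min_gc=0.9))
        assert len(none) == 0


def simple_annotation():
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [10_000, 50_000],
        "end": [20_000, 60_000],
        "strand": ["+", "-"],
        "id": ["g1", "g2"],
    })
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [9_900], "end": [10_400]})
    ann = GenomeAnnotation(genes=genes, cgis=cgis,
                           chrom_lengths={"chr1": 100_000})
    ann.recompute_intergenic()
    return ann


class TestTss:
    def test_strand_aware_tss_tes(self):
        ann = simple_annotation()
        assert ann.tss()["pos"].tolist() == [10_000, 59_999]
        assert ann.tes()["pos"].tolist() == [19_999, 50_000]

    def test_classify_tss_in_out(self):
        ann = simple_annotation()
        inside, outside = rf.classify_tss(ann)
        assert inside["id"].tolist() == ["g1"]
        assert outside["id"].tolist() == ["g2"]

    def test_boundary_is_outside(self):
        ann = simple_annotation()
        ann.cgis = pd.DataFrame({"chrom": ["chr1"], "start": [9_000],
                                 "end": [10_000]})  # half-open: TSS at end
        inside, outside = rf.classify_tss(ann)
        assert len(inside) == 0 and len(outside) == 2


class TestFoldByDistance:
    def test_uniform_map_flat_profile(self):
        w = rf.smooth_windows(uniform_map(400_000, 200, 0.01), 2000)
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [200_000]})
        prof = rf.fold_by_distance(w, pts, max_dist=50_000)
        np.testing.assert_allclose(prof.values[~np.isnan(prof.values)], 1.0,
                                   rtol=1e-9)

    def test_peak_at_planted_points(self):
        rows = [("chr1", i * 200, (i + 1) * 200, 0.01) for i in range(2500)]
        center = 249_000  # midpoint of the window-aligned hotspot
        for i in range(2500):
            s = i * 200
            if 248_000 <= s < 250_000:  # one full 2-kb window elevated 10x
                rows[i] = ("chr1", s, s + 200, 0.1)
        w = rf.smooth_windows(make_map(rows), 2000)
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [center]})
        prof = rf.fold_by_distance(w, pts, max_dist=50_000)
        assert prof.values[0] == pytest.approx(10.0, rel=0.05)

    def test_point_at_chromosome_end_one_sided(self):
        w = rf.smooth_windows(uniform_map(200_000, 200, 0.01), 2000)
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [0]})
        prof = rf.fold_by_distance(w, pts, max_dist=50_000)
        assert np.isfinite(prof.values[0])

    def test_empty_points_rejected(self):
        w = rf.smooth_windows(uniform_map(), 2000)
        with pytest.raises(ValueError, match="empty"):
            rf.fold_by_distance(w, pd.DataFrame(columns=["chrom", "pos"]))


class TestRateByFeature:
    def test_uniform_map_unit_folds(self):
        ann = simple_annotation()
        w = rf.smooth_windows(uniform_map(100_000, 200, 0.01), 2000)
        folds = rf.rate_by_feature(w, ann.feature_intervals())
        for v in folds.values():
            assert v == pytest.approx(1.0, rel=1e-9)

    def test_doubled_in_genes(self):
        ann = simple_annotation()
        rows = []
        for i in range(500):
            s = i * 200
            in_gene = (10_000 <= s < 20_000) or (50_000 <= s < 60_000)
            rows.append(("chr1", s, s + 200, 0.02 if in_gene else 0.01))
        w = rf.smooth_windows(make_map(rows), 2000)
        folds = rf.rate_by_feature(
            w, {"genes": ann.genes[["chrom", "start", "end"]],
                "intergenic": ann.intergenic})
        assert folds["genes"] == pytest.approx(2.0, rel=1e-9)
        assert folds["intergenic"] == pytest.approx(1.0)

    def test_matches_per_bp_oracle(self, rng):
        n = 300
        rows = [("chr1", i * 200, (i + 1) * 200, float(rng.gamma(1, 0.01)))
                for i in range(n)]
        m = make_map(rows)
        w = rf.smooth_windows(m, 200)  # window == interval: no averaging loss
        starts = np.sort(rng.choice(n * 200 - 3000, size=8, replace=False))
        feats = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 2500})
        feats = iv.merge_intervals(feats)
        inter = iv.complement(feats, {"chr1": n * 200})
        folds = rf.rate_by_feature(w, {"f": feats, "intergenic": inter})
        per_bp = np.concatenate([np.full(200, r) for r in m.df["rho"]])
        mask = np.zeros(n * 200, dtype=bool)
        for _, row in feats.iterrows():
            mask[row["start"]:row["end"]] = True
        oracle = per_bp[mask].mean() / per_bp[~mask].mean()
        assert folds["f"] == pytest.approx(oracle, rel=1e-9)

    def test_scale_invariance(self, rng):
        ann = simple_annotation()
        rows = [("chr1", i * 200, (i + 1) * 200, float(rng.gamma(1, 0.01)))
                for i in range(500)]
        w1 = rf.smooth_windows(make_map(rows), 2000)
        rows10 = [(c, s, e, 10 * r) for c, s, e, r in rows]
        w2 = rf.smooth_windows(make_map(rows10), 2000)
        f1 = rf.rate_by_feature(w1, ann.feature_intervals())
        f2 = rf.rate_by_feature(w2, ann.feature_intervals())
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9)


class TestHotspotDensity:
    def test_no_hotspots_zero_everywhere(self):
        ann = simple_annotation()
        hs = rf.HotspotSet(pd.DataFrame(columns=["chrom", "start", "end",
                                                 "peak", "flank_mean", "fold"]),
                           caller="window2kb")
        dens = rf.hotspot_density_by_feature(hs, ann.feature_intervals())
        assert all(v == 0 for v in dens.values())

    def test_all_in_genes(self):
        ann = simple_annotation()
        df = pd.DataFrame({"chrom": ["chr1"], "start": [14_000], "end": [16_000],
                           "peak": [1.0], "flank_mean": [0.1], "fold": [10.0]})
        dens = rf.hotspot_density_by_feature(
            rf.HotspotSet(df, "window2kb"),
            {"genes": ann.genes[["chrom", "start", "end"]],
             "intergenic": ann.intergenic})
        assert dens["genes"] > 0
        assert dens["intergenic"] == 0


class TestTrackCorrelation:
    def test_identical_tracks(self, rng):
        rows = [("chr1", i * 200, (i + 1) * 200, float(rng.gamma(1, 0.01)))
                for i in range(5000)]
        w = rf.smooth_windows(make_map(rows), 100_000)
        rho, p = rf.correlate_tracks(w, w)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranking(self, rng):
        rows = [("chr1", i * 200, (i + 1) * 200, float(i + 1))
                for i in range(5000)]
        a = rf.smooth_windows(make_map(rows), 100_000)
        rows_r = [("chr1", i * 200, (i + 1) * 200, float(5000 - i))
                  for i in range(5000)]
        b = rf.smooth_windows(make_map(rows_r), 100_000)
        rho, _ = rf.correlate_tracks(a, b)
        assert rho == pytest.approx(-1.0)

    def test_independent_tracks_null(self, rng):
        ps = []
        for _ in range(30):
            rows_a = [("chr1", i * 1000, (i + 1) * 1000, float(rng.gamma(1, 1)))
                      for i in range(50)]
            rows_b = [("chr1", i * 1000, (i + 1) * 1000, float(rng.gamma(1, 1)))
                      for i in range(50)]
            a = rf.smooth_windows(make_map(rows_a), 1000)
            b = rf.smooth_windows(make_map(rows_b), 1000)
            rho, p = rf.correlate_tracks(a, b)
            ps.append(p)
        assert np.mean(np.array(ps) <= 0.05) < 0.25  # no systematic signal

    def test_too_few_windows_rejected(self):
        w = rf.smooth_windows(uniform_map(4000, 200, 0.01), 1000)
        with pytest.raises(ValueError, match="10 paired"):
            rf.correlate_tracks(w, w)


class TestProfileAroundHotspots:
    def _hs(self, centers):
        df = pd.DataFrame({"chrom": "chr1",
                           "start": [c - 1000 for c in centers],
                           "end": [c + 1000 for c in centers],
                           "peak": 1.0, "flank_mean": 0.1, "fold": 10.0})
        return rf.HotspotSet(df, "window2kb")

    def test_constant_track_flat(self):
        track = rf.smooth_windows(uniform_map(200_000, 200, 0.01), 2000)
        edges, means, base = rf.profile_around_hotspots(track, self._hs([100_000]))
        np.testing.assert_allclose(means[np.isfinite(means)], 0.01)
        assert base == pytest.approx(0.01)

    def test_elevated_at_hotspots(self):
        rows = [("chr1", i * 200, (i + 1) * 200,
                 0.05 if abs(i * 200 - 100_000) < 1000 else 0.01)
                for i in range(1000)]
        track = rf.smooth_windows(make_map(rows), 2000)
        edges, means, base = rf.profile_around_hotspots(track, self._hs([100_000]))
        assert means[0] > means[-1]

    def test_span_must_be_multiple(self):
        track = rf.smooth_windows(uniform_map(), 2000)
        with pytest.raises(ValueError, match="multiple"):
            rf.profile_around_hotspots(track, self._hs([50_000]), span=2500)
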