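"""Genomic-feature context for recombination landscapes.

CpG-island prediction suited to teleost genomes (CpG observed/expected
ratio only, no GC-content floor by default), strand-aware TSS/TES
handling, fold-by-distance profiles, per-feature rate and hotspot-density
summaries, windowed-track correlations, and covariate profiles around
hotspots.

CGI dialect. The predictor follows cpgplot-style semantics: a window of
``window`` bp slides by 1; each position is scored by the average of all
covering windows; positions whose averaged obs/exp CpG >= ``min_oe`` and
averaged GC >= ``min_gc`` are merged into maximal runs, and runs of at
least ``minlen`` bp are reported. obs/exp for a window is
(#CpG * window) / (#C * #G), defined as 0 when the window has no C or no
G. N bases are excluded from all counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from recfin import intervals as iv
from recfin.hotspots import HotspotSet
from recfin.maps import WindowedMap


@dataclass
class CgiParams:
    window: int = 500
    minlen: int = 250
    min_oe: float = 0.6
    min_gc: float = 0.0

    def __post_init__(self):
        if self.window < 1 or self.minlen < 1:
            raise ValueError("window and minlen must be >= 1")
        if self.min_oe < 0 or self.min_gc < 0:
            raise ValueError("thresholds must be >= 0")


def predict_cgis(seq: str, params: CgiParams | None = None,
                 chrom: str = "chr") -> pd.DataFrame:
    """Predict CpG islands in one sequence; returns chrom/start/end intervals."""
    params = params or CgiParams()
    w = params.window
    n = len(seq)
    if n < w:
        warnings.warn(f"sequence shorter than window ({n} < {w}): no prediction")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def winsum(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[w:] - c[:-w]

    nc = winsum(is_c)
    ng = winsum(is_g)
    # a CpG straddling the window edge counts in the window holding its C
    ncpg = winsum(is_cpg)
    denom = nc * ng
    oe = np.where(denom > 0, ncpg * w / np.where(denom > 0, denom, 1), 0.0)
    gc = (nc + ng) / w

    # per-position average over all covering windows
    nwin = n - w + 1
    lo = np.maximum(np.arange(n) - w + 1, 0)
    hi = np.minimum(np.arange(n), nwin - 1)
    cov_count = hi - lo + 1

    def posavg(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(x)])
        return (c[hi + 1] - c[lo]) / cov_count

    ok = (posavg(oe) >= params.min_oe) & (posavg(gc) >= params.min_gc)
    # maximal runs of qualifying positions, length filter
    edges = np.diff(np.concatenate([[0], ok.astype(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    keep = (ends - starts) >= params.minlen
    return pd.DataFrame({
        "chrom": chrom, "start": starts[keep], "end": ends[keep],
    })


@dataclass
class GenomeAnnotation:
    """Strand-aware gene models plus CGI, TE, and intergenic tracks."""

    genes: pd.DataFrame  # chrom, start, end, strand, id
    cgis: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))
    te: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))
    intergenic: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def tss(self) -> pd.DataFrame:
        """TSS points: gene start on '+', gene end - 1 on '-' (half-open)."""
        plus = self.genes["strand"] == "+"
        pos = np.where(plus, self.genes["start"], self.genes["end"] - 1)
        return pd.DataFrame({"chrom": self.genes["chrom"], "pos": pos,
                             "id": self.genes["id"]}).reset_index(drop=True)

    def tes(self) -> pd.DataFrame:
        """TES points: gene end - 1 on '+', gene start on '-'."""
        plus = self.genes["strand"] == "+"
        pos = np.where(plus, self.genes["end"] - 1, self.genes["start"])
        return pd.DataFrame({"chrom": self.genes["chrom"], "pos": pos,
                             "id": self.genes["id"]}).reset_index(drop=True)

    def recompute_intergenic(self) -> None:
        occupied = pd.concat([self.genes[["chrom", "start", "end"]],
                              self.te[["chrom", "start", "end"]]],
                             ignore_index=True)
        self.intergenic = iv.complement(occupied, self.chrom_lengths)

    def feature_intervals(self, point_flank: int = 1000) -> dict[str, pd.DataFrame]:
        """Labeled interval sets: genes, CGIs, TEs, TSS/TES +-1 kb, intergenic."""
        def around(points: pd.DataFrame) -> pd.DataFrame:
            df = pd.DataFrame({
                "chrom": points["chrom"],
                "start": np.maximum(points["pos"] - point_flank, 0),
                "end": points["pos"] + point_flank + 1,
            })
            return iv.sort_intervals(df)

        out = {
            "genes": self.genes[["chrom", "start", "end"]],
            "intergenic": self.intergenic,
            "tss": around(self.tss()),
            "tes": around(self.tes()),
        }
        if len(self.cgis):
            out["cgis"] = self.cgis[["chrom", "start", "end"]]
        if len(self.te):
            out["te"] = self.te[["chrom", "start", "end"]]
        return out


def classify_tss(ann: GenomeAnnotation) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split TSS points into those inside vs outside a CGI (half-open)."""
    tss = ann.tss()
    if len(ann.cgis) == 0:
        return tss.iloc[0:0], tss
    inside = iv.points_in_intervals(tss, ann.cgis)
    return tss[inside].reset_index(drop=True), tss[~inside].reset_index(drop=True)


@dataclass
class FoldProfile:
    """Mean rate per distance bin, scaled by the rate at the reference distance."""

    bin_edges: np.ndarray  # length n_bins + 1, in bp
    values: np.ndarray  # scaled means, reference bin = 1
    reference_rate: float  # unscaled mean in the outermost bin


def fold_by_distance(wmap: WindowedMap, points: pd.DataFrame,
                     max_dist: int = 50000, bin_width: int = 2000) -> FoldProfile:
    """Rate as a function of distance to the nearest point (TSS/TES set).

    Each non-missing window is assigned the distance from its midpoint to
    the nearest point; windows are binned by distance out to ``max_dist``
    and bin means are scaled by the outermost (reference) bin.
    """
    if len(points) == 0:
        raise ValueError("empty point set")
    track = wmap.as_track()
    dist = iv.nearest_point_distance(track, points)
    rho = track["rho"].to_numpy(dtype=float)
    weight = track["covered"].to_numpy(dtype=float)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    idx = np.digitize(dist, edges) - 1
    n_bins = len(edges) - 1
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if weight[sel].sum() > 0:
            means[b] = np.average(rho[sel], weights=weight[sel])
    if np.isnan(means[-1]) or means[-1] <= 0:
        raise ValueError("no windows at the reference distance")
    return FoldProfile(bin_edges=edges, values=means / means[-1],
                       reference_rate=float(means[-1]))


def rate_by_feature(wmap: WindowedMap,
                    features: dict[str, pd.DataFrame]) -> dict[str, float]:
    """bp-weighted mean rate per feature class, scaled by the intergenic mean."""
    if "intergenic" not in features:
        raise ValueError("features must include an 'intergenic' class")
    track = wmap.as_track()
    means = {name: iv.weighted_mean_over(track, ivs, "rho")
             for name, ivs in features.items()}
    base = means["intergenic"]
    if not np.isfinite(base) or base <= 0:
        raise ValueError("intergenic mean is zero or undefined")
    return {name: m / base for name, m in means.items()}


def hotspot_density_by_feature(hs: HotspotSet,
                               features: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Hotspot midpoints per Mb of each feature class."""
    mids = pd.DataFrame({
        "chrom": hs.df["chrom"],
        "pos": (hs.df["start"] + hs.df["end"]) // 2,
    })
    out = {}
    for name, ivs in features.items():
        length = iv.total_length(iv.merge_intervals(ivs))
        if length <= 0:
            raise ValueError(f"feature class {name!r} has zero length")
        count = int(iv.points_in_intervals(mids, ivs).sum()) if len(hs) else 0
        out[name] = count / (length / 1e6)
    return out


def correlate_tracks(wmap: WindowedMap, track: WindowedMap) -> tuple[float, float]:
    """Spearman rank correlation between two windowed tracks on shared windows."""
    a = wmap.df.set_index(["chrom", "start"])["rho"]
    b = track.df.set_index(["chrom", "start"])["rho"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    if len(joined) < 10:
        raise ValueError("fewer than 10 paired windows")
    res = stats.spearmanr(joined["a"], joined["b"])
    return float(res.statistic), float(res.pvalue)


def profile_around_hotspots(track: WindowedMap, hs: HotspotSet,
                            span: int = 10000) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean covariate per distance bin from the nearest hotspot center.

    Returns (bin edges, bin means, genomic mean baseline). Bin width is the
    track's window width; ``span`` must be a multiple of it.
    """
    if span % track.width != 0:
        raise ValueError("span must be a multiple of the track window width")
    centers = pd.DataFrame({
        "chrom": hs.df["chrom"],
        "pos": (hs.df["start"] + hs.df["end"]) // 2,
    })
    sub = track.as_track()
    dist = iv.nearest_point_distance(sub, centers)
    vals = sub["rho"].to_numpy(dtype=float)
    edges = np.arange(0, span + track.width, track.width)
    idx = np.digitize(dist, edges) - 1
    means = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            means[b] = vals[sel].mean()
    baseline = float(np.nanmean(vals))
    return edges, means, baseline
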