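"""Landscape-level summaries of population recombination maps.

Covers run averaging with convergence diagnostics, window smoothing,
genome-wide rates, Lorenz-style heterogeneity curves ("what fraction of
total recombination sits in the top q of the genome"), chromosome-scale
percentile profiles (the telomeric U-shape), and the small arithmetic
around population parameters (Ne = theta / 4 mu, the mu/r ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from recfin import intervals as iv
from recfin.maps import RhoMap, WindowedMap


@dataclass
class PopulationParams:
    """Population-genetic scalars: theta = 4*Ne*mu per bp, mu per bp per
    generation, pedigree-based r in cM/Mb, and the implied Ne."""

    theta: float = float("nan")
    mu: float = float("nan")
    r_cm_per_mb: float = float("nan")
    ne: float = float("nan")


def mu_over_r(mu: float, r_cm_per_mb: float) -> float:
    """Dimensionless mu/r with r converted from cM/Mb to per-bp Morgans.

    1 cM/Mb = 1e-8 recombination events per bp per generation.
    """
    if r_cm_per_mb <= 0:
        raise ValueError("r must be > 0")
    return mu / (r_cm_per_mb * 1e-8)


def estimate_ne(theta: float, mu: float) -> float:
    """Effective population size from nucleotide diversity: Ne = theta / (4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return theta / (4.0 * mu)


def genome_wide_rate(rmap: RhoMap) -> float:
    """bp-weighted mean rho: sum(rho_i * len_i) / sum(len_i)."""
    if len(rmap) == 0:
        raise ValueError("empty map")
    lens = rmap.lengths
    return float((rmap.df["rho"].to_numpy() * lens).sum() / lens.sum())


def average_runs(maps: list[RhoMap]) -> tuple[RhoMap, np.ndarray]:
    """Average independent inference runs sharing one interval skeleton.

    Returns the per-interval arithmetic mean map and the matrix of pairwise
    Spearman rank correlations between runs (the convergence diagnostic).
    """
    if len(maps) < 1:
        raise ValueError("need at least one map")
    skel = maps[0].df[["chrom", "start", "end"]]
    for m in maps[1:]:
        if not m.df[["chrom", "start", "end"]].equals(skel):
            raise ValueError("maps do not share an identical interval skeleton")
    rhos = np.column_stack([m.df["rho"].to_numpy() for m in maps])
    mean_df = skel.copy()
    mean_df["rho"] = rhos.mean(axis=1)
    k = rhos.shape[1]
    corr = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = stats.spearmanr(rhos[:, i], rhos[:, j]).statistic
            corr[i, j] = corr[j, i] = r
    return RhoMap(mean_df), corr


def smooth_windows(rmap: RhoMap, width: int) -> WindowedMap:
    """Average a map into fixed windows; bp-weighted within each window.

    Tail windows shorter than ``width`` at chromosome ends are kept.
    Windows with no SNP-interval coverage are flagged missing (NaN).
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    rows = []
    covs = iv.coverages(rmap.df, "rho")
    for chrom, length in rmap.chrom_lengths().items():
        edges = np.arange(0, length + width, width)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        w, l = covs[chrom].span_sums(edges[:-1].astype(float), edges[1:].astype(float))
        rho = np.where(l > 0, w / np.where(l > 0, l, 1.0), np.nan)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": edges[:-1], "end": edges[1:],
            "rho": rho, "covered": l,
        }))
    return WindowedMap(pd.concat(rows, ignore_index=True), width=width)


@dataclass
class HeterogeneityCurve:
    """Cumulative recombination fraction vs genome fraction, best-first.

    ``x`` is the cumulative bp fraction when intervals are visited in order
    of decreasing rho; ``y`` the cumulative fraction of total rho*bp. The
    curve starts at (0, 0), ends at (1, 1), and majorizes the diagonal.
    """

    x: np.ndarray
    y: np.ndarray

    def fraction_in_top(self, q: float) -> float:
        """Fraction of total recombination in the hottest fraction q of the genome."""
        if not 0 <= q <= 1:
            raise ValueError("q must be in [0, 1]")
        return float(np.interp(q, self.x, self.y))


def heterogeneity_curve(rmap: RhoMap) -> HeterogeneityCurve:
    if len(rmap) == 0:
        raise ValueError("empty map")
    lens = rmap.lengths.astype(float)
    rho = rmap.df["rho"].to_numpy(dtype=float)
    total = (rho * lens).sum()
    if total <= 0:
        raise ValueError("all-zero map: heterogeneity curve undefined")
    order = np.argsort(-rho, kind="mergesort")
    cl = np.cumsum(lens[order]) / lens.sum()
    cr = np.cumsum((rho * lens)[order]) / total
    return HeterogeneityCurve(
        x=np.concatenate([[0.0], cl]), y=np.concatenate([[0.0], cr])
    )


def chromosome_percentile_profile(wmap: WindowedMap, n_bins: int = 30) -> np.ndarray:
    """Mean rate in equal-length chromosome bins, averaged across chromosomes
    and scaled by the genomic mean; telomeric elevation shows as raised ends."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    covs = iv.coverages(wmap.as_track(), "rho")
    per_chrom = []
    for chrom, length in wmap.chrom_lengths().items():
        if chrom not in covs:
            continue
        edges = np.linspace(0.0, float(length), n_bins + 1)
        w, l = covs[chrom].span_sums(edges[:-1], edges[1:])
        per_chrom.append(np.where(l > 0, w / np.where(l > 0, l, 1.0), np.nan))
    if not per_chrom:
        raise ValueError("no covered chromosomes")
    prof = np.nanmean(np.vstack(per_chrom), axis=0)
    return prof / wmap.genome_wide_rate()
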