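"""Interval arithmetic on sorted, non-overlapping genomic intervals.

All coordinates are 0-based half-open. Interval tables are pandas
DataFrames with at least ``chrom``, ``start``, ``end`` columns; value
tracks additionally carry a value column (``rho`` or similar).

The workhorse is :class:`Coverage`, a pair of prefix-sum step functions
(value*bp and covered bp accumulated along a chromosome) that turns
bp-weighted means over arbitrary spans into O(log n) lookups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ("chrom", "start", "end")


def check_sorted_disjoint(df: pd.DataFrame, what: str = "intervals") -> None:
    """Raise ValueError unless intervals are sorted and non-overlapping per chrom."""
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if np.any(e <= s):
            raise ValueError(f"{what}: empty or inverted interval on {chrom}")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"{what}: overlapping or unsorted intervals on {chrom}")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping intervals, per chromosome."""
    if len(df) == 0:
        return pd.DataFrame(columns=list(COLUMNS))
    out = []
    for chrom, sub in sort_intervals(df).groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:
                cur_e = max(cur_e, e[i])
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s[i], e[i]
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=list(COLUMNS))


def complement(df: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Complement of (merged) intervals within the given chromosome bounds."""
    merged = merge_intervals(df) if len(df) else df
    out = []
    by_chrom = dict(tuple(merged.groupby("chrom", sort=False))) if len(merged) else {}
    for chrom, length in chrom_lengths.items():
        pos = 0
        if chrom in by_chrom:
            for _, row in by_chrom[chrom].iterrows():
                if row["start"] > pos:
                    out.append((chrom, pos, min(row["start"], length)))
                pos = max(pos, row["end"])
        if pos < length:
            out.append((chrom, pos, length))
    return pd.DataFrame(out, columns=list(COLUMNS))


def total_length(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


@dataclass
class Coverage:
    """Prefix-sum step functions over one chromosome's sorted disjoint intervals."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    _cum_w: np.ndarray = None  # value*bp accumulated over full intervals
    _cum_l: np.ndarray = None

    def __post_init__(self):
        lens = (self.ends - self.starts).astype(float)
        self._cum_w = np.concatenate([[0.0], np.cumsum(self.values * lens)])
        self._cum_l = np.concatenate([[0.0], np.cumsum(lens)])

    def weight_upto(self, x) -> np.ndarray:
        """Total value*bp over map positions < x (vectorized in x)."""
        x = np.asarray(x, dtype=float)
        i = np.searchsorted(self.ends, x, side="right")
        full = self._cum_w[i]
        partial = np.where(
            (i < len(self.starts)) & (np.take(self.starts, i, mode="clip") < x),
            np.take(self.values, i, mode="clip")
            * (x - np.take(self.starts, i, mode="clip")),
            0.0,
        )
        return full + partial

    def length_upto(self, x) -> np.ndarray:
        """Covered bp over map positions < x (vectorized in x)."""
        x = np.asarray(x, dtype=float)
        i = np.searchsorted(self.ends, x, side="right")
        full = self._cum_l[i]
        partial = np.where(
            (i < len(self.starts)) & (np.take(self.starts, i, mode="clip") < x),
            x - np.take(self.starts, i, mode="clip"),
            0.0,
        )
        return full + partial

    def span_sums(self, a, b) -> tuple[np.ndarray, np.ndarray]:
        """(value*bp, covered bp) over [a, b) — vectorized."""
        return (
            self.weight_upto(b) - self.weight_upto(a),
            self.length_upto(b) - self.length_upto(a),
        )


def coverages(df: pd.DataFrame, value_col: str) -> dict[str, Coverage]:
    """Per-chromosome Coverage objects for a value track; NaN rows dropped."""
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        ok = sub[value_col].notna()
        sub = sub[ok]
        if len(sub) == 0:
            continue
        out[chrom] = Coverage(
            sub["start"].to_numpy(dtype=float),
            sub["end"].to_numpy(dtype=float),
            sub[value_col].to_numpy(dtype=float),
        )
    return out


def weighted_mean_over(
    track: pd.DataFrame, intervals: pd.DataFrame, value_col: str = "rho"
) -> float:
    """bp-weighted mean of a value track over a set of query intervals.

    Overlapping query intervals are merged first so no bp is counted twice.
    Returns NaN when the track does not cover any queried bp.
    """
    covs = coverages(track, value_col)
    merged = merge_intervals(intervals)
    w = l = 0.0
    for chrom, sub in merged.groupby("chrom", sort=False):
        if chrom not in covs:
            continue
        dw, dl = covs[chrom].span_sums(
            sub["start"].to_numpy(dtype=float), sub["end"].to_numpy(dtype=float)
        )
        w += dw.sum()
        l += dl.sum()
    return w / l if l > 0 else float("nan")


def per_interval_means(
    track: pd.DataFrame, intervals: pd.DataFrame, value_col: str = "rho"
) -> np.ndarray:
    """bp-weighted track mean for each query interval (NaN where uncovered)."""
    covs = coverages(track, value_col)
    out = np.full(len(intervals), np.nan)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        if chrom not in covs:
            continue
        dw, dl = covs[chrom].span_sums(
            sub["start"].to_numpy(dtype=float), sub["end"].to_numpy(dtype=float)
        )
        vals = np.where(dl > 0, dw / np.where(dl > 0, dl, 1.0), np.nan)
        out[sub.index.to_numpy()] = vals
    return out


def points_in_intervals(
    points: pd.DataFrame, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean array: does each (chrom, pos) point fall inside an interval?

    Half-open convention: a point at an interval end is outside.
    """
    merged = merge_intervals(intervals)
    by_chrom = {c: s for c, s in merged.groupby("chrom", sort=False)}
    hit = np.zeros(len(points), dtype=bool)
    for chrom, sub in points.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        ivs = by_chrom[chrom]
        s = ivs["start"].to_numpy()
        e = ivs["end"].to_numpy()
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(s, pos, side="right") - 1
        ok = (idx >= 0) & (pos < np.take(e, idx, mode="clip"))
        hit[sub.index.to_numpy()] = ok
    return hit


def has_overlap(query: pd.DataFrame, other: pd.DataFrame, min_bp: int = 1) -> np.ndarray:
    """For each query interval: does it overlap some `other` interval by >= min_bp?"""
    merged = merge_intervals(other)
    by_chrom = {c: s for c, s in merged.groupby("chrom", sort=False)}
    out = np.zeros(len(query), dtype=bool)
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        ivs = by_chrom[chrom]
        os = ivs["start"].to_numpy()
        oe = ivs["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        res = np.zeros(len(sub), dtype=bool)
        lo = np.searchsorted(oe, qs, side="right")
        hi = np.searchsorted(os, qe, side="left")
        for k in range(len(sub)):
            best = 0
            for j in range(lo[k], hi[k]):
                best = max(best, min(qe[k], oe[j]) - max(qs[k], os[j]))
                if best >= min_bp:
                    break
            res[k] = best >= min_bp
        out[sub.index.to_numpy()] = res
    return out


def nearest_point_distance(
    queries: pd.DataFrame, points: pd.DataFrame, pos_col: str = "pos"
) -> np.ndarray:
    """Distance from each query midpoint to the nearest point on its chromosome.

    Queries lacking any point on their chromosome get +inf.
    """
    by_chrom = {
        c: np.sort(s[pos_col].to_numpy()) for c, s in points.groupby("chrom", sort=False)
    }
    out = np.full(len(queries), np.inf)
    for chrom, sub in queries.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        pts = by_chrom[chrom]
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        i = np.searchsorted(pts, mid)
        left = np.where(i > 0, mid - np.take(pts, np.maximum(i - 1, 0)), np.inf)
        right = np.where(i < len(pts), np.take(pts, np.minimum(i, len(pts) - 1)) - mid, np.inf)
        out[sub.index.to_numpy()] = np.minimum(np.abs(left), np.abs(right))
    return out
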