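"""Hotspot sharing between populations and species.

The observed statistic is the number of hotspots in the smaller of two
sets that overlap the other set by at least ``min_bp``, expressed as a
percentage of the smaller set. Significance comes from a masked
random-placement null: the same number of fixed-width spots is dropped
uniformly into the allowed (unmasked) genome, and the overlap with the
real partner set is recorded per permutation.

The genome mask excludes regions where LD-based hotspot calls are
unreliable or trivially shared: extreme nucleotide-diversity windows,
the very top of the rho distribution, the largest assembly gaps, and the
hotspots themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from recfin import intervals as iv
from recfin.hotspots import HotspotSet
from recfin.maps import RhoMap, WindowedMap


def overlap_sets(a: HotspotSet, b: HotspotSet, min_bp: int = 1) -> tuple[int, float]:
    """Shared-hotspot count and percentage, smaller set as denominator.

    An interval overlapping two partners counts once. Returns
    (n_shared, percent_shared).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty hotspot set")
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    shared = iv.has_overlap(small.intervals(), large.intervals(), min_bp=min_bp)
    n_shared = int(shared.sum())
    return n_shared, 100.0 * n_shared / len(small)


@dataclass
class GenomeMask:
    """Excluded intervals (with reasons) and the allowed complement."""

    excluded: pd.DataFrame  # chrom, start, end, reason
    allowed: pd.DataFrame  # chrom, start, end
    chrom_lengths: dict[str, int]

    def allowed_bp(self) -> int:
        return iv.total_length(self.allowed)


def build_mask(
    rmap: RhoMap,
    diversity: WindowedMap | None = None,
    gaps: pd.DataFrame | None = None,
    hs: HotspotSet | None = None,
    q_div: tuple[float, float] = (0.025, 0.975),
    q_rho_top: float = 0.001,
    q_gap_top: float = 0.10,
    chrom_lengths: dict[str, int] | None = None,
) -> GenomeMask:
    """Assemble the exclusion mask used by the permutation null."""
    chrom_lengths = chrom_lengths or rmap.chrom_lengths()
    parts = []

    if diversity is not None:
        track = diversity.as_track()
        vals = track["rho"].to_numpy(dtype=float)
        lo, hi = np.quantile(vals, q_div)
        bad = track[(vals < lo) | (vals > hi)]
        if len(bad):
            parts.append(bad[["chrom", "start", "end"]].assign(reason="diversity"))

    rho = rmap.df["rho"].to_numpy(dtype=float)
    cut = np.quantile(rho, 1.0 - q_rho_top)
    hot = rmap.df[rho > cut]
    if len(hot):
        parts.append(hot[["chrom", "start", "end"]].assign(reason="extreme_rho"))

    if gaps is not None and len(gaps):
        glen = (gaps["end"] - gaps["start"]).to_numpy()
        cut = np.quantile(glen, 1.0 - q_gap_top)
        big = gaps[glen >= cut]
        if len(big):
            parts.append(big[["chrom", "start", "end"]].assign(reason="gap"))

    if hs is not None and len(hs):
        parts.append(hs.intervals().assign(reason="hotspot"))

    if parts:
        excluded = iv.sort_intervals(pd.concat(parts, ignore_index=True))
    else:
        excluded = pd.DataFrame(columns=["chrom", "start", "end", "reason"])
    allowed = iv.complement(excluded[["chrom", "start", "end"]], chrom_lengths)
    return GenomeMask(excluded=excluded, allowed=allowed, chrom_lengths=chrom_lengths)


@dataclass
class OverlapResult:
    n_shared: int
    percent_shared: float
    null: np.ndarray
    p_value: float
    n_permutations: int


def _sample_spot_starts(
    rng: np.random.Generator,
    n_intervals: int,
    width: int,
    seg_gstart: np.ndarray,
    cum_eff: np.ndarray,
    retry_cap: int,
) -> np.ndarray:
    """Uniform mutually non-overlapping spot starts, in global coordinates.

    Segments are given by their global start and the cumulative count of
    admissible start positions; spots always fit entirely in one segment,
    so they can never cross a segment (or chromosome) boundary.
    """
    import bisect

    total = int(cum_eff[-1])
    kept: list[int] = []
    tries = 0
    while len(kept) < n_intervals:
        if tries > retry_cap:
            raise RuntimeError("random spot placement infeasible: retry cap hit")
        tries += 1
        u = int(rng.integers(0, total))
        si = int(np.searchsorted(cum_eff, u, side="right"))
        s = int(seg_gstart[si]) + (u - (int(cum_eff[si - 1]) if si > 0 else 0))
        i = bisect.bisect_left(kept, s)
        if i > 0 and kept[i - 1] + width > s:
            continue
        if i < len(kept) and s + width > kept[i]:
            continue
        kept.insert(i, s)
    return np.asarray(kept, dtype=np.int64)


def _place_random_spots(
    rng: np.random.Generator,
    n_intervals: int,
    width: int,
    seg_chrom: np.ndarray,
    seg_start: np.ndarray,
    eff: np.ndarray,
    retry_cap: int,
) -> pd.DataFrame:
    """Place n non-overlapping width-bp spots uniformly in allowed segments."""
    # map segments onto a disjoint global axis so one draw locates a spot
    seg_bounds = np.concatenate([[0], np.cumsum(eff + width)])
    starts = _sample_spot_starts(rng, n_intervals, width,
                                 seg_bounds[:-1], np.cumsum(eff), retry_cap)
    si = np.searchsorted(seg_bounds[1:], starts, side="right")
    local = starts - seg_bounds[si]
    df = pd.DataFrame({
        "chrom": seg_chrom[si],
        "start": seg_start[si] + local,
    })
    df["end"] = df["start"] + width
    return iv.sort_intervals(df)


def _to_global_axis(
    intervals: pd.DataFrame,
    seg_chrom: np.ndarray,
    seg_start: np.ndarray,
    eff: np.ndarray,
    seg_bounds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Clip intervals to the allowed segments and map them onto the padded
    global axis used for spot placement. Spots always lie inside segments,
    so clipping loses no overlap."""
    if len(intervals) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    width_pad = int(seg_bounds[1] - seg_bounds[0] - eff[0]) if len(eff) else 0
    by_chrom = {c: s for c, s in intervals.groupby("chrom", sort=False)}
    gs_list, ge_list = [], []
    for i in range(len(seg_chrom)):
        sub = by_chrom.get(seg_chrom[i])
        if sub is None:
            continue
        a = int(seg_start[i])
        b = a + int(eff[i]) + width_pad - 1  # segment length = eff + width - 1
        s = np.maximum(sub["start"].to_numpy(), a)
        e = np.minimum(sub["end"].to_numpy(), b)
        keep = e > s
        if keep.any():
            shift = int(seg_bounds[i]) - a
            gs_list.append(s[keep] + shift)
            ge_list.append(e[keep] + shift)
    if not gs_list:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    gs = np.concatenate(gs_list)
    ge = np.concatenate(ge_list)
    order = np.argsort(gs)
    return gs[order], ge[order]


def _count_min_bp(gs: np.ndarray, width: int, ostarts: np.ndarray,
                  oends: np.ndarray, min_bp: int) -> int:
    count = 0
    for s in gs:
        e = s + width
        lo = int(np.searchsorted(oends, s, side="right"))
        hi = int(np.searchsorted(ostarts, e, side="left"))
        for j in range(lo, hi):
            if min(e, oends[j]) - max(s, ostarts[j]) >= min_bp:
                count += 1
                break
    return count


def permutation_null(
    n_intervals: int,
    width: int,
    mask: GenomeMask,
    other: HotspotSet,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_bp: int = 1,
    observed: int | None = None,
) -> OverlapResult:
    """Null distribution of shared counts for randomly placed spots.

    Per permutation, ``n_intervals`` non-overlapping width-bp spots are
    placed uniformly in the allowed space (never intersecting the mask;
    rejection sampling with a 100x retry cap) and their overlap count
    with ``other`` is recorded. When the ``observed`` count of the real
    set is supplied, the empirical p-value uses the +1 correction:
    (1 + #{null >= observed}) / (1 + n_perm).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    allowed = mask.allowed
    segs = allowed[(allowed["end"] - allowed["start"]) >= width]
    if len(segs) == 0:
        raise ValueError("mask leaves no segment wide enough for a spot")
    eff = (segs["end"] - segs["start"] - width + 1).to_numpy(dtype=np.int64)
    if int((segs["end"] - segs["start"]).sum()) < n_intervals * width:
        raise ValueError("allowed space cannot hold the requested spots")
    seg_chrom = segs["chrom"].to_numpy()
    seg_start = segs["start"].to_numpy()

    # work on a disjoint global axis (segments padded by `width`) so both
    # placement and overlap counting are plain searchsorted operations
    seg_bounds = np.concatenate([[0], np.cumsum(eff + width)])
    cum_eff = np.cumsum(eff)
    other_iv = iv.merge_intervals(other.intervals())
    ostarts, oends = _to_global_axis(other_iv, seg_chrom, seg_start, eff,
                                     seg_bounds)
    retry_cap = 100 * max(n_intervals, 1)
    counts = np.empty(n_perm, dtype=np.int64)
    for k in range(n_perm):
        gs = _sample_spot_starts(rng, n_intervals, width, seg_bounds[:-1],
                                 cum_eff, retry_cap)
        if len(ostarts) == 0:
            counts[k] = 0
        elif min_bp == 1:
            i = np.searchsorted(oends, gs, side="right")
            hit = (i < len(ostarts)) & (np.take(ostarts, i, mode="clip") < gs + width)
            counts[k] = int(hit.sum())
        else:
            counts[k] = _count_min_bp(gs, width, ostarts, oends, min_bp)
    if observed is None and len(other_iv) == 0:
        observed = 0
    if observed is not None:
        p = float((1.0 + np.sum(counts >= observed)) / (1.0 + n_perm))
        pct = 100.0 * observed / n_intervals if n_intervals else float("nan")
    else:
        p, pct, observed = float("nan"), float("nan"), -1
    return OverlapResult(
        n_shared=int(observed), percent_shared=pct, null=counts,
        p_value=p, n_permutations=n_perm,
    )


def sharing_test(
    a: HotspotSet,
    b: HotspotSet,
    mask: GenomeMask,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_bp: int = 1,
    width: int | None = None,
) -> OverlapResult:
    """Observed sharing of a vs b plus its masked random-placement null.

    Random spots replace the smaller set (same count, fixed width, default
    the smaller set's median width) and are compared with the real larger
    set each permutation.
    """
    n_shared, pct = overlap_sets(a, b, min_bp=min_bp)
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    if width is None:
        width = int(np.median(small.widths()))
    return permutation_null(len(small), width, mask, large, n_perm=n_perm,
                            seed=seed, min_bp=min_bp, observed=n_shared)


def lift_hotspots(hs: HotspotSet, lift_table: pd.DataFrame) -> tuple[HotspotSet, int]:
    """Map hotspots through homologous collinear blocks to another assembly.

    ``lift_table`` columns: q_chrom, q_start, q_end, t_chrom, t_start,
    t_end; query and target block lengths must match. Hotspots not fully
    contained in one query block are dropped; the dropped count is
    returned alongside.
    """
    qlen = lift_table["q_end"] - lift_table["q_start"]
    tlen = lift_table["t_end"] - lift_table["t_start"]
    if not (qlen == tlen).all():
        raise ValueError("lift table blocks must have equal query/target lengths")
    out = []
    dropped = 0
    by_chrom = {c: s.sort_values("q_start") for c, s in lift_table.groupby("q_chrom", sort=False)}
    for _, row in hs.df.iterrows():
        blocks = by_chrom.get(row["chrom"])
        lifted = None
        if blocks is not None:
            qs = blocks["q_start"].to_numpy()
            i = int(np.searchsorted(qs, row["start"], side="right")) - 1
            if i >= 0:
                blk = blocks.iloc[i]
                if row["start"] >= blk["q_start"] and row["end"] <= blk["q_end"]:
                    off = row["start"] - blk["q_start"]
                    w = row["end"] - row["start"]
                    lifted = (blk["t_chrom"], int(blk["t_start"] + off),
                              int(blk["t_start"] + off + w))
        if lifted is None:
            dropped += 1
        else:
            out.append((*lifted, row["peak"], row["flank_mean"], row["fold"]))
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "peak",
                                    "flank_mean", "fold"])
    return HotspotSet(iv.sort_intervals(df), caller=hs.caller), dropped


def compare_rate_classes(
    rmap: RhoMap, classes: dict[str, pd.DataFrame]
) -> dict:
    """Kruskal-Wallis across per-interval mean rho by class, then pairwise
    two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment."""
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    samples: dict[str, np.ndarray] = {}
    for name, ivs in classes.items():
        vals = iv.per_interval_means(rmap.df, ivs.reset_index(drop=True), "rho")
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(f"class {name!r} has fewer than 2 covered intervals")
        samples[name] = vals
    names = list(samples)
    kw = stats.kruskal(*samples.values())
    pairs, raw_p = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mw = stats.mannwhitneyu(samples[names[i]], samples[names[j]],
                                    alternative="two-sided")
            pairs.append((names[i], names[j]))
            raw_p.append(mw.pvalue)
    adj = stats.false_discovery_control(raw_p, method="bh") if raw_p else []
    return {
        "omnibus_stat": float(kw.statistic),
        "omnibus_p": float(kw.pvalue),
        "pairwise": [
            {"a": a, "b": b, "p_raw": float(p), "p_adj": float(q)}
            for (a, b), p, q in zip(pairs, raw_p, adj)
        ],
    }
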