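"""PWM scanning with exact p-value thresholds, hotspot enrichment, and the
between-lineage motif-erosion permutation test.

Scores are log-odds in bits: log2((p + pseudocount)/background), with the
pseudocount (default 0.1) renormalised per column. The null score
distribution under the background model is computed exactly by dynamic
programming over scores discretised at 0.01-bit bins, FIMO-style: the
score threshold for a p-value cutoff is the smallest discretised score
whose tail probability is <= the cutoff. Scanning discretises with the
same bins, so the threshold and the scanner agree exactly.

The erosion test compares mean motif counts between two genome lineages
restricted to collinear blocks. Its null distribution shuffles the PWM
column order (preserving information content), re-thresholds, and
recounts; the null statistic is the between-lineage difference in mean
occurrence, compared two-sided by default against the observed
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

ALPHABET = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

BIN_BITS = 0.01  # score discretisation, in bits


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (incl. N) -> -1."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class Pwm:
    """Position weight matrix over ACGT with a background model."""

    probs: np.ndarray  # (W, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1
    name: str = "motif"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (W, 4)")
        if np.any(np.abs(self.probs.sum(axis=1) - 1) > 1e-9):
            raise ValueError("PWM columns must sum to 1")
        if abs(self.background.sum() - 1) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(W, 4) log2 odds with renormalised pseudocount."""
        p = (self.probs + self.pseudocount)
        p /= p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    def int_scores(self, bin_bits: float = BIN_BITS) -> np.ndarray:
        """Log-odds discretised to integer multiples of ``bin_bits``."""
        return np.round(self.log_odds() / bin_bits).astype(np.int64)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.probs[::-1, ::-1].copy(), self.background[::-1].copy(),
                   self.pseudocount, self.name + "_rc")

    def permute_columns(self, rng: np.random.Generator) -> "Pwm":
        order = rng.permutation(self.width)
        return Pwm(self.probs[order], self.background, self.pseudocount,
                   self.name + "_perm")

    def to_meme(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\n")
            fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*self.background))
            fh.write(f"MOTIF {self.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.width}\n")
            for row in self.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_meme(cls, path: str | Path, name: str | None = None) -> "Pwm":
        """Read the first (or named) motif from a MEME minimal-format file."""
        background = np.full(4, 0.25)
        rows: list[list[float]] = []
        motif_name = None
        with open(path) as fh:
            lines = iter(fh.read().splitlines())
        in_matrix = False
        for line in lines:
            s = line.strip()
            if s.startswith("Background letter frequencies"):
                freq_line = next(lines).split()
                background = np.array([float(freq_line[i]) for i in (1, 3, 5, 7)])
            elif s.startswith("MOTIF"):
                cur = s.split()[1]
                if motif_name is not None and rows:
                    break
                if name is None or cur == name:
                    motif_name = cur
                in_matrix = False
            elif s.startswith("letter-probability matrix") and motif_name:
                in_matrix = True
            elif in_matrix and s:
                parts = s.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                else:
                    in_matrix = False
        if motif_name is None or not rows:
            raise ValueError(f"no motif found in {path}")
        probs = np.array(rows)
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(probs, background, name=motif_name)


def score_distribution(pwm: Pwm, bin_bits: float = BIN_BITS
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact discretised null distribution of scores under the background.

    Returns (integer score grid, probability per grid point).
    """
    ints = pwm.int_scores(bin_bits)
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    span = hi - lo + 1
    # distribution over (partial score - running minimum), convolved per column
    work = np.zeros(span)
    work[0] = 1.0
    for col in range(pwm.width):
        col_lo = int(ints[col].min())
        nxt = np.zeros(span)
        for a in range(4):
            s = int(ints[col, a]) - col_lo  # shift so increments are >= 0
            w = float(pwm.background[a])
            if w == 0.0:
                continue
            if s == 0:
                nxt += w * work
            else:
                nxt[s:] += w * work[:span - s]
        work = nxt
    grid = np.arange(lo, hi + 1)
    return grid, work


def score_threshold(pwm: Pwm, p_cut: float = 1e-7,
                    bin_bits: float = BIN_BITS) -> float:
    """Smallest score (bits) whose exact background tail probability <= p_cut.

    When ``p_cut`` undercuts the attainable resolution (every word scores
    above it), the maximum score is returned with a warning; downstream
    scans then keep only perfect-scoring windows.
    """
    if not 0 < p_cut <= 1:
        raise ValueError("p_cut must be in (0, 1]")
    grid, probs = score_distribution(pwm, bin_bits)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = tail <= p_cut
    if not ok.any():
        warnings.warn("p_cut below attainable tail resolution; "
                      "threshold set to the maximum score")
        return float(grid[-1] * bin_bits)
    return float(grid[np.argmax(ok)] * bin_bits)


def tail_probability(pwm: Pwm, score_bits: float,
                     bin_bits: float = BIN_BITS) -> float:
    """Exact P(score >= score_bits) under the background model."""
    grid, probs = score_distribution(pwm, bin_bits)
    t = int(np.round(score_bits / bin_bits))
    return float(probs[grid >= t].sum())


def _window_scores(code: np.ndarray, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores for every window plus a validity mask (no N)."""
    w = ints.shape[0]
    n = len(code) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(code < 0, 0, code)
    for j in range(w):
        col = code[j:j + n]
        scores += ints[j][safe[j:j + n]]
        valid &= col >= 0
    return scores, valid


def scan(seq: str, pwm: Pwm, threshold: float,
         bin_bits: float = BIN_BITS) -> pd.DataFrame:
    """Scan both strands; returns hits as (pos, strand, score_bits).

    ``pos`` is the 0-based start of the W-bp window on the forward strand.
    Windows containing non-ACGT bases are skipped. Same-position hits on
    opposite strands are both reported.
    """
    code = encode(seq)
    t_int = int(np.round(threshold / bin_bits))
    frames = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        ints = mat.int_scores(bin_bits)
        scores, valid = _window_scores(code, ints)
        hit = valid & (scores >= t_int)
        idx = np.flatnonzero(hit)
        frames.append(pd.DataFrame({
            "pos": idx, "strand": strand,
            "score_bits": scores[idx] * bin_bits,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"]).reset_index(drop=True)


def count_hits(seq: str, pwm: Pwm, threshold: float,
               blocks: pd.DataFrame | None = None,
               bin_bits: float = BIN_BITS) -> int:
    """Number of hits, optionally restricted to windows inside block intervals."""
    hits = scan(seq, pwm, threshold, bin_bits)
    if blocks is None or len(blocks) == 0:
        if blocks is not None and len(blocks) == 0:
            return 0
        return len(hits)
    w = pwm.width
    starts = np.sort(blocks["start"].to_numpy())
    ends = blocks.sort_values("start")["end"].to_numpy()
    pos = hits["pos"].to_numpy()
    i = np.searchsorted(starts, pos, side="right") - 1
    inside = (i >= 0) & (pos + w <= np.take(ends, i, mode="clip"))
    return int(inside.sum())


def count_in_blocks(genomes: dict[str, str], blocks: dict[str, pd.DataFrame],
                    pwm: Pwm, threshold: float,
                    bin_bits: float = BIN_BITS) -> dict[str, int]:
    """Per-genome motif counts restricted to that genome's collinear blocks."""
    return {name: count_hits(seq, pwm, threshold, blocks.get(name), bin_bits)
            for name, seq in genomes.items()}


@dataclass
class ErosionResult:
    mean_a: float
    mean_b: float
    percent_reduction: float  # 100 * (mean_a - mean_b) / mean_a
    observed_diff: float  # mean_a - mean_b, the statistic tested
    null: np.ndarray  # null diffs from PWM column permutations
    p_value: float
    n_permutations: int
    two_sided: bool


def erosion_statistics(counts_a: list[int], counts_b: list[int]
                       ) -> tuple[float, float, float]:
    """(mean_a, mean_b, percent reduction of lineage B relative to A)."""
    ma = float(np.mean(counts_a))
    mb = float(np.mean(counts_b))
    if ma == 0:
        raise ValueError("reference lineage has zero mean count")
    return ma, mb, 100.0 * (ma - mb) / ma


def erosion_test(
    counts_a: list[int],
    counts_b: list[int],
    pwm: Pwm,
    genomes_a: dict[str, str],
    genomes_b: dict[str, str],
    blocks: dict[str, pd.DataFrame] | None = None,
    p_cut: float = 1e-7,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    two_sided: bool = True,
    bin_bits: float = BIN_BITS,
) -> ErosionResult:
    """Motif-erosion permutation test between two genome lineages.

    The observed statistic is the difference in mean motif count between
    lineages (reported alongside as a percent reduction of the reference
    lineage A). Each permutation shuffles the PWM's column order,
    recomputes the score threshold at the same p-value cutoff, recounts
    in every genome, and records the between-lineage difference. The
    empirical p-value uses the +1 correction and is two-sided on the
    difference by default.
    """
    if len(counts_a) < 2 or len(counts_b) < 2:
        raise ValueError("need >= 2 genomes per lineage")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ma, mb, pct = erosion_statistics(counts_a, counts_b)
    obs = ma - mb
    blocks = blocks or {}
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = pwm.permute_columns(rng)
        thr = score_threshold(perm, p_cut, bin_bits)
        ca = [count_hits(s, perm, thr, blocks.get(n), bin_bits)
              for n, s in genomes_a.items()]
        cb = [count_hits(s, perm, thr, blocks.get(n), bin_bits)
              for n, s in genomes_b.items()]
        null[k] = float(np.mean(ca)) - float(np.mean(cb))
    if two_sided:
        extreme = np.abs(null) >= abs(obs)
    else:
        extreme = null >= obs
    p = float((1.0 + extreme.sum()) / (1.0 + n_perm))
    return ErosionResult(mean_a=ma, mean_b=mb, percent_reduction=pct,
                         observed_diff=obs, null=null, p_value=p,
                         n_permutations=n_perm, two_sided=two_sided)


@dataclass
class EnrichmentResult:
    fold: float
    p_value: float
    frac_hotspot: float
    frac_control: float
    retained: bool  # fold >= 2 and found in >= 5% of hotspots


def enrichment_at_hotspots(
    hot_present: np.ndarray, ctrl_present: np.ndarray,
    min_fold: float = 2.0, min_frac: float = 0.05,
) -> EnrichmentResult:
    """Motif enrichment in hotspot vs control sequences (Fisher exact test).

    Arguments are boolean arrays: does each sequence carry >= 1 hit.
    fold = hotspot hit fraction / control hit fraction.
    """
    hot_present = np.asarray(hot_present, dtype=bool)
    ctrl_present = np.asarray(ctrl_present, dtype=bool)
    if len(hot_present) == 0 or len(ctrl_present) == 0:
        raise ValueError("both sequence sets must be non-empty")
    fh = hot_present.mean()
    fc = ctrl_present.mean()
    fold = float("inf") if fc == 0 and fh > 0 else (fh / fc if fc > 0 else 1.0)
    table = [[int(hot_present.sum()), int((~hot_present).sum())],
             [int(ctrl_present.sum()), int((~ctrl_present).sum())]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return EnrichmentResult(fold=float(fold), p_value=p,
                            frac_hotspot=float(fh), frac_control=float(fc),
                            retained=bool(fold >= min_fold and fh >= min_frac))


def gc_fraction(seq: str) -> float:
    code = encode(seq)
    acgt = code >= 0
    if not acgt.any():
        return float("nan")
    return float(np.isin(code, (1, 2)).sum() / acgt.sum())


def sample_gc_matched_controls(
    genome: dict[str, str],
    hotspot_gc: np.ndarray,
    allowed: pd.DataFrame,
    width: int = 2000,
    n_per_target: int = 10,
    bin_width: float = 0.025,
    seed: int | np.random.Generator = 0,
    max_draw_factor: int = 200,
) -> pd.DataFrame:
    """Random control intervals whose GC histogram matches the hotspots'.

    The hotspot GC values are binned at ``bin_width``; for each bin,
    ``n_per_target`` times the hotspot count is drawn from the allowed
    (masked) genome by rejection sampling. Returns chrom/start/end/gc.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hotspot_gc = np.asarray(hotspot_gc, dtype=float)
    bins = np.floor(hotspot_gc / bin_width).astype(int)
    quota: dict[int, int] = {}
    for b in bins:
        quota[b] = quota.get(b, 0) + n_per_target
    segs = allowed[(allowed["end"] - allowed["start"]) >= width]
    if len(segs) == 0:
        raise ValueError("allowed space has no segment wide enough")
    eff = (segs["end"] - segs["start"] - width + 1).to_numpy(dtype=np.int64)
    cum = np.cumsum(eff)
    seg_chrom = segs["chrom"].to_numpy()
    seg_start = segs["start"].to_numpy()
    need = sum(quota.values())
    out = []
    tries = 0
    cap = max_draw_factor * need
    while need > 0:
        if tries > cap:
            raise RuntimeError("GC-matched control sampling: insufficient "
                               "allowed space for some GC bins")
        tries += 1
        u = rng.integers(0, cum[-1])
        si = int(np.searchsorted(cum, u, side="right"))
        off = int(u - (cum[si - 1] if si > 0 else 0))
        chrom = seg_chrom[si]
        s = int(seg_start[si] + off)
        gc = gc_fraction(genome[chrom][s:s + width])
        if np.isnan(gc):
            continue
        b = int(np.floor(gc / bin_width))
        if quota.get(b, 0) > 0:
            quota[b] -= 1
            need -= 1
            out.append((chrom, s, s + width, gc))
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "gc"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def centrality_test(
    hit_positions: np.ndarray,
    center_window: int,
    total_window: int,
    smooth_window: int = 250,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One-tailed binomial test for central concentration of motif hits.

    ``hit_positions`` are offsets in [0, total_window) within sequences
    centred on the hotspot. Under the null, a hit lands in the central
    ``center_window`` with probability center_window/total_window. Also
    returns a positional density smoothed with a triangular window.
    """
    if total_window <= center_window:
        raise ValueError("total_window must exceed center_window")
    pos = np.asarray(hit_positions)
    n = len(pos)
    lo = (total_window - center_window) / 2
    hi = (total_window + center_window) / 2
    k = int(((pos >= lo) & (pos < hi)).sum())
    if n == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(k, n, center_window / total_window,
                                  alternative="greater").pvalue)
    counts = np.bincount(pos.astype(int), minlength=total_window).astype(float)
    half = smooth_window // 2
    kern = np.concatenate([np.arange(1, half + 2), np.arange(half, 0, -1)]).astype(float)
    kern /= kern.sum()
    density = np.convolve(counts, kern, mode="same")
    grid = np.arange(total_window) - total_window // 2
    return p, grid, density
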