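"""Synthetic inputs with the statistical structure the analyses assume.

The generator emulates the building blocks of a salmonid population
recombination study: inter-SNP rho landscapes with gamma-distributed
background, smoothly telomere-elevated broad-scale rates and embedded
~2-kb hotspots of chosen fold; gene/CGI/TE annotations; hypervariable
PRDM9 zinc-finger allele panels; and genome pairs in which one lineage
carries a stated fraction of disrupted motif instances.

All randomness flows through one explicitly passed numpy Generator; a
fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from recfin import intervals as iv
from recfin.features import GenomeAnnotation
from recfin.maps import RhoMap
from recfin.motif import Pwm, encode, ALPHABET
from recfin.zf import CONTACT_POSITIONS, UNIT_LEN, ZfAlleleSet, catalogue_alleles


@dataclass
class SyntheticGenomeSpec:
    chrom_lengths: dict[str, int]
    gc: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be > 0")
        if not 0 < self.gc < 1:
            raise ValueError("GC target must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class HotspotPlanEntry:
    chrom: str
    center: int
    width: int = 2000
    fold: float = 10.0

    def interval(self) -> tuple[int, int]:
        return self.center - self.width // 2, self.center + self.width - self.width // 2


def _check_plan(plan: list[HotspotPlanEntry], chrom_lengths: dict[str, int]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for entry in plan:
        if entry.chrom not in chrom_lengths:
            raise ValueError(f"planned hotspot on unknown chromosome {entry.chrom}")
        if not 0 <= entry.center < chrom_lengths[entry.chrom]:
            raise ValueError("hotspot center outside chromosome")
        if entry.width <= 0:
            raise ValueError("hotspot width must be > 0")
        if entry.fold < 1:
            raise ValueError("hotspot fold must be >= 1")
        by_chrom.setdefault(entry.chrom, []).append(entry.interval())
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping planned hotspots on {chrom}")


def telomere_multiplier(mid: np.ndarray, length: int, fold: float,
                        edge_frac: float = 0.2) -> np.ndarray:
    """Cosine ramp from 1 at mid-chromosome to ``fold`` at the ends.

    The ramp spans the outer ``edge_frac`` of chromosome length on each
    side; the central region sits at 1.
    """
    d = np.minimum(mid, length - mid).astype(float)
    edge = edge_frac * length
    ramp = np.where(d < edge, 0.5 * (1 + np.cos(np.pi * d / edge)), 0.0)
    return 1.0 + (fold - 1.0) * ramp


def gen_rho_landscape(
    spec: SyntheticGenomeSpec,
    snp_density: float = 1 / 200,
    background_mean: float = 0.005,
    background_shape: float = 1.0,
    telomere_fold: float = 1.0,
    plan: list[HotspotPlanEntry] | None = None,
    rng: np.random.Generator | None = None,
) -> RhoMap:
    """Simulate an inter-SNP rho map.

    SNP positions follow a homogeneous Poisson process at ``snp_density``
    per bp. Each inter-SNP interval draws rho from a gamma distribution
    with shape ``background_shape`` scaled to ``background_mean``, then
    multiplied by a positional factor: a cosine telomere ramp (up to
    ``telomere_fold`` at chromosome ends) times the planned hotspot fold
    wherever the interval midpoint lies inside a planned hotspot.
    """
    if snp_density <= 0:
        raise ValueError("snp_density must be > 0")
    if background_mean <= 0 or background_shape <= 0:
        raise ValueError("background mean and shape must be > 0")
    plan = plan or []
    _check_plan(plan, spec.chrom_lengths)
    rng = rng or spec.rng()
    frames = []
    for chrom, length in spec.chrom_lengths.items():
        n_snps = rng.poisson(snp_density * length)
        if n_snps < 2:
            raise ValueError(f"too few SNPs simulated on {chrom}; raise snp_density")
        pos = np.unique(rng.integers(0, length, size=n_snps))
        starts, ends = pos[:-1], pos[1:]
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        rho = rng.gamma(background_shape,
                        background_mean / background_shape, size=len(starts))
        mid = (starts + ends) // 2
        mult = telomere_multiplier(mid, length, telomere_fold)
        for entry in plan:
            if entry.chrom != chrom:
                continue
            s, e = entry.interval()
            inside = (mid >= s) & (mid < e)
            mult[inside] *= entry.fold
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "rho": rho * mult,
        }))
    return RhoMap(pd.concat(frames, ignore_index=True)).validate()


def plan_random_hotspots(
    spec: SyntheticGenomeSpec,
    n: int,
    width: int = 2000,
    fold: float = 10.0,
    rng: np.random.Generator | None = None,
    margin: int = 50000,
) -> list[HotspotPlanEntry]:
    """Place n non-overlapping planned hotspots uniformly, away from ends."""
    rng = rng or spec.rng()
    chroms = list(spec.chrom_lengths)
    weights = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    plan: list[HotspotPlanEntry] = []
    tries = 0
    while len(plan) < n:
        if tries > 1000 * n:
            raise RuntimeError("cannot place non-overlapping hotspots")
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = spec.chrom_lengths[chrom]
        lo, hi = margin + width, length - margin - width
        if hi <= lo:
            continue
        center = int(rng.integers(lo, hi))
        s, e = center - width // 2, center + width - width // 2
        if any(s < pe + width and ps - width < e for ps, pe in placed[chrom]):
            continue
        placed[chrom].append((s, e))
        plan.append(HotspotPlanEntry(chrom, center, width, fold))
    return plan


def gen_annotation(
    spec: SyntheticGenomeSpec,
    n_genes: int = 200,
    cgi_at_tss_frac: float = 0.5,
    te_frac: float = 0.3,
    gene_len_range: tuple[int, int] = (2000, 10000),
    rng: np.random.Generator | None = None,
) -> GenomeAnnotation:
    """Random non-overlapping genes with strands, CGIs at a fraction of
    TSSs, TE intervals covering about ``te_frac``, and the intergenic
    complement of genes and TEs."""
    if not 0 <= cgi_at_tss_frac <= 1 or not 0 <= te_frac <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = rng or spec.rng()
    genome_len = sum(spec.chrom_lengths.values())
    mean_gene = sum(gene_len_range) / 2
    if n_genes * mean_gene > 0.6 * genome_len:
        raise ValueError("n_genes infeasible for genome size")
    # allocate genes to chromosomes proportionally to length
    chroms = list(spec.chrom_lengths)
    weights = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n_genes, weights / weights.sum())
    gene_rows = []
    gid = 0
    for chrom, k in zip(chroms, alloc):
        length = spec.chrom_lengths[chrom]
        lens = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=k)
        free = length - int(lens.sum())
        if free < k + 1:
            raise ValueError("n_genes infeasible for genome size")
        # distribute the leftover space as random inter-gene gaps
        cuts = np.sort(rng.choice(free, size=k, replace=False))
        pos = 0
        prev_cut = 0
        for gl, cut in zip(lens, cuts):
            pos += int(cut - prev_cut)
            prev_cut = cut
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((chrom, pos, pos + int(gl), strand, f"g{gid:05d}"))
            gid += 1
            pos += int(gl)
    genes = pd.DataFrame(gene_rows,
                         columns=["chrom", "start", "end", "strand", "id"])
    genes = iv.sort_intervals(genes)

    ann = GenomeAnnotation(genes=genes, chrom_lengths=dict(spec.chrom_lengths))
    # CGIs overlapping a fraction of TSSs (span TSS-200 .. TSS+300)
    tss = ann.tss()
    pick = rng.random(len(tss)) < cgi_at_tss_frac
    chrom_len = tss["chrom"][pick].map(spec.chrom_lengths)
    cgi = pd.DataFrame({
        "chrom": tss["chrom"][pick],
        "start": np.maximum(tss["pos"][pick] - 200, 0),
        "end": np.minimum(tss["pos"][pick] + 300, chrom_len),
    })
    ann.cgis = iv.merge_intervals(cgi) if len(cgi) else cgi

    # TE intervals: fixed 500-bp elements dropped until coverage ~ te_frac
    te_rows = []
    te_len = 500
    for chrom, length in spec.chrom_lengths.items():
        target = int(te_frac * length)
        n_te = target // te_len
        if n_te > 0:
            starts = np.sort(rng.choice(length - te_len, size=n_te, replace=False))
            te_rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": starts + te_len}))
    te = (iv.merge_intervals(pd.concat(te_rows, ignore_index=True))
          if te_rows else pd.DataFrame(columns=["chrom", "start", "end"]))
    ann.te = te
    ann.recompute_intergenic()
    return ann


# ---------------------------------------------------------------------------
# zinc-finger allele panels

_BASE_UNIT = "TGEKPYECKECGKAFSQSSHLIRHQRTH"  # X7-CXXC-X12-HXXXH scaffold
_SCAFFOLD_1BASED = (8, 11, 24, 28)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def gen_zf_alleles(
    n_alleles: int = 10,
    n_units_range: tuple[int, int] = (5, 10),
    contact_variability: float = 0.5,
    seed: int | np.random.Generator = 0,
    degenerate_last: bool = False,
    carriers_per_allele: int = 2,
) -> ZfAlleleSet:
    """Simulate a panel of ZF-array alleles.

    Each allele concatenates 28-residue C2H2 units derived from a common
    scaffold; substitutions hit the four DNA-contact positions at rate
    ``contact_variability`` and every other non-scaffold position at a
    10x lower rate. With ``degenerate_last`` the final histidine of the
    last unit is replaced (H -> Y), mimicking the non-functional terminal
    finger seen in real arrays.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if not 0 <= contact_variability <= 1:
        raise ValueError("contact_variability must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contact = set(CONTACT_POSITIONS)
    scaffold = set(_SCAFFOLD_1BASED)
    obs = []
    for a in range(n_alleles):
        n_units = int(rng.integers(n_units_range[0], n_units_range[1] + 1))
        units = []
        for u in range(n_units):
            residues = list(_BASE_UNIT)
            for p in range(1, UNIT_LEN + 1):
                if p in scaffold:
                    continue
                rate = contact_variability if p in contact else contact_variability / 10
                if rng.random() < rate:
                    choices = [x for x in _AA20 if x != residues[p - 1]]
                    residues[p - 1] = choices[int(rng.integers(len(choices)))]
            units.append("".join(residues))
        if degenerate_last:
            last = units[-1]
            units[-1] = last[:-1] + "Y"
        seq = "".join(units)
        for c in range(carriers_per_allele):
            obs.append((f"ind{a}_{c}", seq))
    return catalogue_alleles(obs, species="synthetic")


# ---------------------------------------------------------------------------
# motif-erosion genome pairs

_IDX2BASE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def random_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _IDX2BASE[idx].tobytes().decode()


@dataclass
class ErodedGenomes:
    """Two genome lineages sharing planted motif instances, lineage B eroded."""

    genomes_a: dict[str, str]
    genomes_b: dict[str, str]
    blocks: dict[str, pd.DataFrame]  # per-genome collinear blocks
    planted_positions: np.ndarray
    eroded_positions: np.ndarray
    pwm: Pwm


def gen_eroded_genomes(
    base: str,
    pwm: Pwm,
    n_instances: int,
    n_per_lineage: tuple[int, int] = (5, 5),
    erosion_frac: float = 0.05,
    neutral_rate: float = 1e-4,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
) -> ErodedGenomes:
    """Plant motif instances in a base sequence and erode one lineage.

    The PWM consensus is written at ``n_instances`` non-overlapping
    positions. Lineage A genomes keep all instances; in lineage B a fixed
    subset of ``erosion_frac`` of the instances (shared by the whole
    lineage, as expected for a population-level erosion event) is
    disrupted by one substitution at the highest-information PWM column.
    Independent neutral substitutions are added per genome outside the
    planted windows. Collinear blocks span each full genome.
    """
    if not 0 <= erosion_frac <= 1:
        raise ValueError("erosion_frac must be in [0, 1]")
    w = pwm.width
    if w > len(base):
        raise ValueError("PWM wider than any plantable region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = len(base)
    spacing = length // n_instances
    if spacing <= 2 * w:
        raise ValueError("base sequence too short for that many instances")
    offsets = rng.integers(0, spacing - w, size=n_instances)
    positions = np.arange(n_instances) * spacing + offsets
    consensus = pwm.consensus()
    arr = np.frombuffer(base.upper().encode(), dtype=np.uint8).copy()
    cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for p in positions:
        arr[p:p + w] = cons_arr
    planted = arr

    info_col = int(np.argmax((pwm.probs * np.log2(
        np.maximum(pwm.probs, 1e-12) / pwm.background)).sum(axis=1)))
    best = int(pwm.probs[info_col].argmax())
    worst = int(pwm.probs[info_col].argmin())
    if worst == best:
        worst = (best + 2) % 4
    n_eroded = int(round(erosion_frac * n_instances))
    eroded = rng.choice(n_instances, size=n_eroded, replace=False)
    eroded_positions = positions[np.sort(eroded)]

    in_motif = np.zeros(length, dtype=bool)
    for p in positions:
        in_motif[p:p + w] = True
    neutral_sites = np.flatnonzero(~in_motif)

    def make_genome(erode: bool, g: np.random.Generator) -> str:
        a = planted.copy()
        if erode:
            for p in eroded_positions:
                a[p + info_col] = _IDX2BASE[worst]
        n_mut = g.poisson(neutral_rate * len(neutral_sites))
        if n_mut > 0:
            sites = g.choice(neutral_sites, size=n_mut, replace=False)
            shift = g.integers(1, 4, size=n_mut)
            codes = encode(a.tobytes().decode())
            new = (codes[sites] + shift) % 4
            a[sites] = _IDX2BASE[new]
        return a.tobytes().decode()

    genomes_a = {f"A{i}": make_genome(False, rng) for i in range(n_per_lineage[0])}
    genomes_b = {f"B{i}": make_genome(True, rng) for i in range(n_per_lineage[1])}
    blocks = {name: pd.DataFrame({"chrom": [chrom], "start": [0], "end": [length]})
              for name in list(genomes_a) + list(genomes_b)}
    return ErodedGenomes(genomes_a=genomes_a, genomes_b=genomes_b,
                         blocks=blocks, planted_positions=positions,
                         eroded_positions=eroded_positions, pwm=pwm)
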