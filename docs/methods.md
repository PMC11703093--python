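# Methods

This note documents the models, parameter choices and numerical
conventions behind `recfin`, and what the synthetic-data generator does
and does not emulate.

## Coordinates and containers

All coordinates are 0-based, half-open, everywhere. BED input/output is
used as-is; GFF3 gene rows are converted on read. A recombination map
(`RhoMap`) is a set of sorted, non-overlapping inter-SNP intervals with a
per-bp population recombination rate ρ = 4N·r, as produced by LD-based
inference; a `WindowedMap` is the same landscape averaged into fixed
windows tiling each chromosome. Windows without any SNP-interval
coverage are *missing* (NaN), never zero — zeroing them would bias every
downstream bp-weighted mean. Tail windows shorter than the nominal width
at chromosome ends are kept and bp-weighted.

All weighted means run through per-chromosome prefix-sum step functions
(`intervals.Coverage`): the ρ·bp mass and covered bp accumulated along
the chromosome, so the mean over any span is two O(log n) lookups. This
makes the central conservation invariant exact to rounding: the total
ρ·bp mass is unchanged by smoothing, averaging or re-windowing (the test
suite asserts relative error ≤ 1e-9; in practice it is ~1e-15).

## Landscape statistics

- `genome_wide_rate` is the bp-weighted mean Σρ·len / Σlen.
- `heterogeneity_curve` sorts intervals by ρ descending and accumulates
  (bp fraction, recombination fraction): a Lorenz-type curve from (0,0)
  to (1,1), concave by construction. `fraction_in_top(q)` interpolates
  linearly between curve points, because interval granularity makes an
  exact 20% cut unattainable otherwise. Whether such a statistic is
  computed on raw inter-SNP intervals or on 2-kb windows is a real
  dialect choice; both are exposed (pass a windowed map re-expressed as a
  `RhoMap` for the windowed flavor).
- `chromosome_percentile_profile` splits each chromosome into n equal
  bins (default 30), bp-weights within bins, averages bins across
  chromosomes and scales by the genomic mean; telomere-elevated
  landscapes show the classic U shape.
- `average_runs` requires identical interval skeletons and reports the
  pairwise Spearman matrix used as the convergence diagnostic for
  independent MCMC runs (the conventional acceptance bar is > 0.96).
- Population arithmetic: N = θ/4μ and μ/r with the pedigree rate
  converted at 1 cM/Mb = 1e-8 events/bp/generation. Reported ratios are
  conventionally rounded to two decimals.

## Hotspot calling

Both callers use the same qualification rule: a candidate (inter-SNP
interval or 2-kb window) qualifies when its rate is at least `fold`
(default 5) times the bp-weighted mean rate of the flanking 50 kb on
each side. Design choices, where the field convention is ambiguous:

- The candidate itself is excluded from its flank mean; including it
  would dilute the statistic.
- The flank is 50 kb *per side* (configurable to a total span).
- Near chromosome ends, the available one-sided flank is used.
- Missing windows never qualify and break runs of consecutive
  qualifying windows.
- Raw caller: maximal runs of consecutive qualifying intervals merge
  into one hotspot; the merged span is then re-audited against its own
  flanks and kept only if peak ≥ fold × flank mean, so every reported
  hotspot satisfies the definition post hoc.
- Window caller: within each maximal qualifying run only the
  highest-rate window is retained (leftmost on ties — deterministic);
  hotspot coordinates are the fixed window bounds.

Properties worth knowing: raising `fold` never increases the hotspot
count; on synthetic landscapes with ~200-bp SNP spacing the raw caller
recovers > 99% of planted 2-kb fold-10 hotspots, while the window caller
recovers ~65% — a planted hotspot that straddles a window boundary has
its apparent fold halved in both windows, an intrinsic cost of the
fixed-grid definition, not a defect. On a constant-rate landscape both
callers return exactly zero calls. On an iid gamma background the raw
caller has a small intrinsic false-positive rate (single heavy draws),
which mirrors the behavior of per-interval definitions on real LD maps.

## CpG islands and features

The CGI predictor follows cpgplot-style semantics with the teleost
parameterization: window 500 bp sliding by 1; per-window
obs/exp CpG = (#CpG × window)/(#C × #G) (defined as 0 when a window has
no C or no G) and GC fraction; each position is scored by the average of
all covering windows; positions with averaged obs/exp ≥ 0.6 and GC ≥ 0
merge into maximal runs, and runs ≥ 250 bp are reported. The GC floor is
0 by default because teleost CGIs are CpG-rich but not GC-rich; the
averaging dialect is the configurable part. N bases are excluded from
all counts.

Fold-by-distance profiles bin 2-kb windows by distance to the nearest
TSS/TES (2-kb bins out to 50 kb, matching map resolution) and scale by
the outermost bin, so the value at the 50-kb reference is 1 by
construction. Rate-by-feature folds are bp-weighted means per feature
class scaled by the intergenic mean; feature classes may overlap (a CGI
can be genic) — only intergenic is defined exclusively, as the
complement of genes and TEs. "TSS regions" are TSS ± 1 kb.

## Hotspot sharing and the permutation null

Sharing between two hotspot sets is the count of hotspots in the
*smaller* set overlapping the other by ≥ 1 bp (a hotspot overlapping two
partners counts once), expressed as a percentage of the smaller set —
symmetric by construction.

Significance comes from a masked random-placement null: the genome mask
excludes diversity windows outside the 2.5–97.5% quantiles, the top 0.1%
of ρ values, the largest 10% of assembly gaps, and the hotspots
themselves. Per permutation the same number of fixed-width spots is
placed uniformly in the allowed space, mutually non-overlapping
(rejection sampling, retry cap 100×; real hotspots do not overlap
either), and the overlap with the real partner set is recorded.
The empirical p uses the +1 correction, (1 + #{null ≥ obs})/(1 + n_perm),
so it is never exactly zero. Default n_perm is 1,000, with 100 available.
Internally, placement and overlap counting run on a padded "global axis"
concatenating the allowed segments, so each permutation is a handful of
`searchsorted` calls.

Calibration: the empirical p is discrete. When expected overlap counts
are small (a handful), ties plus the +1 correction make the test
conservative (attained size well under the nominal 5%); with expected
overlaps of ~10+ the p-value is near-uniform. The calibration suite
therefore uses 100 and 120 spots on 4 Mb (expected overlap ≈ 12), where
the attained size sits in the 3–6% range.

## Zinc-finger arrays

A C2H2 unit is 28 residues on the scaffold X7-CXXC-X12-HXXXH (C at unit
positions 8 and 11, H at 24 and 28). Arrays are tiled greedily left to
right; a trailing unit whose final histidine is substituted is flagged
degenerate (a non-functional last finger is common), and a 27-residue
unit missing one internal residue is flagged short. Both are excluded
from the diversity profile by default.

Any single-residue difference founds a new allele. Positional diversity
is Gini–Simpson d_i = 1 − Σf², computed by default over the set of
*unique* units — each distinct finger counted once regardless of carrier
frequency, which is the convention for arrays under concerted evolution;
a frequency-weighted mode is available. The DNA-binding ratio
r = Σ d(contact)/Σ d(all) uses contact positions 16, 18, 19, 22
(1-based within the unit), i.e. α-helix −1, +2, +3, +6 for this frame;
the positions are a parameter because the helix register of a 28-mer is
a convention. r is scale-invariant and undefined (an error, not 0) on a
zero-diversity profile.

## PWM scanning and erosion

Scores are log-odds in bits with a per-column pseudocount of 0.1
(renormalized). The exact null score distribution under the background
model is computed by dynamic programming over scores discretized at
0.01-bit bins; the threshold for a p-value cutoff (default 1e-7) is the
smallest binned score whose tail probability is ≤ the cutoff. The
scanner discretizes identically, so threshold and scanner agree exactly;
the DP tail equals exhaustive word enumeration to ~1e-15 for all widths
the enumeration can reach. When the cutoff undercuts the attainable
resolution (4^-W), the threshold is the maximum score and a warning is
issued. Both strands are scanned; windows containing non-ACGT bases are
skipped; block-restricted counts require the whole motif window inside a
block.

The erosion test compares mean motif counts between two genome lineages
on collinear blocks. The observed effect is reported as the percent
reduction of the reference lineage, 100·(m_A − m_B)/m_A. The null
shuffles the PWM's *column order* — composition and information content
preserved, which is the property the null needs — re-thresholds at the
same cutoff and recounts; the null statistic is the between-lineage
difference in mean counts (a percent-of-reference statistic is unstable
under the null, where permuted motifs often have near-zero counts). The
empirical p is two-sided on the difference by default, with a one-sided
option.

GC-matched controls are drawn by binning hotspot GC content at width
0.025 and rejection-sampling the masked genome until each bin's quota
(default 10× the hotspot count) is filled. Central enrichment uses a
one-tailed binomial test of hits in the central window against the
window-length fraction, plus a positional density smoothed with a
250-bp triangular moving average.

## The synthetic-data generator

The generator produces inputs with the statistical structure the
analyses assume; defaults are chosen to resemble a salmonid population
landscape:

- ρ landscape: SNP positions are a homogeneous Poisson process (default
  density 1/200 bp); each inter-SNP interval draws ρ from a gamma with
  shape 1.0 scaled to a background mean of 0.005/bp (within the
  0.003–0.012 range typical of these genomes), multiplied by a cosine
  telomere ramp (1 at mid-chromosome rising to `telomere_fold` over the
  outer 20% of length; reported telomeric elevations are 3–6×, with no
  published functional form) and by the planted fold inside planned
  ~2-kb hotspots. Overlapping planned hotspots are rejected.
- The background is iid across intervals: there is no published
  quantitative model for ρ autocorrelation, so none is imposed. SNP
  density is likewise uncoupled from ρ by default.
- Annotations: non-overlapping genes (2–10 kb) with random strands, a
  CGI overlapping a chosen fraction of TSSs, TE intervals covering a
  target fraction, intergenic as the complement of genes and TEs.
- ZF panels: alleles concatenate 5–10 scaffold units; substitutions hit
  the four contact positions at the chosen rate and all other
  non-scaffold positions at a 10× lower rate; the scaffold C/H positions
  are never touched, so every unit parses. The degenerate last finger is
  implemented as H→Y at the final histidine.
- Eroded genome pairs: the PWM consensus is planted at N non-overlapping
  positions of a random base sequence; lineage A keeps all instances,
  lineage B shares one eroded subset (erosion is a population-level
  event, so the injected percent is exactly recoverable) disrupted by
  one substitution at the highest-information PWM column; per-genome
  neutral substitutions are added outside motif windows; collinear
  blocks span each genome.

All randomness flows through one explicitly passed numpy Generator;
fixed seeds give byte-identical outputs.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: LD-inference noise and its SNP-density
dependence, ρ autocorrelation and linked-selection structure, residual
tetrasomy, TE-family structure, real CGI base composition, and
coalescent haplotype structure. The suite demonstrates that the
estimators recover known inputs under the stated statistical model, not
that the model captures every property of empirical maps.

## Problem sizes used in the automated checks

Chosen so the whole suite runs comfortably on one CPU: hotspot recovery
on a 20-Mb four-chromosome genome with 200 planted fold-10 hotspots;
null calibration over 200 random hotspot-set pairs (100 and 120 spots on
4 Mb, n_perm = 199); erosion recovery on ten 600-kb genomes with 2,000
planted 12-bp motif instances and 100 matrix permutations; the PWM
enumeration oracle over 50 random matrices of width ≤ 6; conservation
and curve geometry over 100 random maps.

## Known limitations

- The window hotspot caller under-recovers hotspots that straddle window
  boundaries (see above); use the raw caller when SNP density allows.
- `lift_hotspots` maps only hotspots fully contained in one collinear
  block and assumes strand-preserving blocks.
- The CGI predictor implements one averaging dialect of the
  sliding-window rule; other tools differ in edge handling by a few bp.
- The erosion test's matrix permutation preserves column composition
  only; nulls that also perturb within-column composition would be
  stricter.
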