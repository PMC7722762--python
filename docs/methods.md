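# Methods

This note describes the models and procedures implemented in `sammyseq`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish about real data.

## Background and scope

Sequential chromatin fractionation sequencing (SAMMY-seq) separates
chromatin into pools of decreasing solubility/accessibility — S2
(DNase-released), S3 (high-salt-released) and S4 (urea-solubilized, most
condensed) — and sequences each pool. Regions enriched in a less
accessible fraction relative to a more accessible one ("SAMMY-seq
domains") mark compacted, heterochromatic, lamina-associated chromatin.
The package implements the downstream analysis: from per-fraction aligned
fragment midpoints to compaction domains, overlap statistics against
reference interval sets (LADs, histone-mark domains), border and TSS
metaprofiles, genome-wide track correlations, chromatin-state-stratified
transcript p-value aggregation, and nuclear-foci periphery proximity.
Raw-read processing (alignment, deduplication, trimming) and differential
expression testing are upstream of this package; it consumes coordinates
and p-value tables.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention), including internal
bin indices: bin `i` of size `b` covers `[i·b, (i+1)·b)` and the final
partial bin of each chromosome is kept. `merge`, `intersect`, `subtract`
and `total_bp` are exact at base-pair resolution (tested against a
per-base bitmap oracle); `merge` joins book-ended intervals, matching
`bedtools merge`. Strand is ignored except for TSS orientation in
metaprofiles.

## Fraction signal

- **Binned coverage**: midpoint counts per fixed bin; optional CPM.
- **Log-ratio track**: `log2(((t_i + c)/T_eff) / ((r_i + c)/R_eff))` with
  `T_eff = library + c·n_bins`. The pseudocount `c = 0.5` reads per bin
  keeps the track finite and scale-invariant; it is recorded in the output
  metadata.
- **Smoothed differential signal**: a Gaussian kernel density difference
  between two read sets evaluated on a regular grid (default bandwidth
  h = 150 bp, step 50 bp, tag shift 0). The kernel is truncated at 8
  standard deviations, where the truncation error is ~1e-14 of the peak —
  numerically indistinguishable from the untruncated sum (oracle-tested).
  The two read sets are accumulated separately and subtracted, so swapping
  them negates the signal bit-exactly. Per-read scaling by library size is
  available via `scale_by_library`.
- **Down-sampling** operates on aligned coordinates as independent
  Bernoulli thinning, which is equivalent in distribution to sampling raw
  reads for everything downstream of alignment.

## Domain calling

The caller follows the enriched-domain-detector (EDD) recipe for broad
megabase-scale domains:

1. bin target and reference libraries; form the log-ratio track;
2. classify informative bins as enriched (+1) or depleted (−G, the gap
   penalty) by a polarity threshold;
3. extract **all maximal-scoring segments** per chromosome with the
   Ruzzo–Tompa algorithm (linear time; exactness verified against
   exhaustive enumeration on small instances);
4. assess segments against a permutation null: informative-bin scores are
   shuffled genome-wide and the **maximum** segment score per permutation
   recorded; segment p = (1 + #{null max ≥ observed}) / (1 + P). This
   maximum-based null is family-wise flavored and conservative. BH
   correction is applied across segments; calls are retained at q ≤ fdr
   **and** informative-bin fraction ≥ 0.98 (default).

**Polarity threshold.** The original tool derives its enriched/depleted
split point from the data; the exact rule is not part of this package's
sources. A strict median split is simple but collapses whenever enriched
bins are the majority: the median then falls inside the enriched mode and
a fraction of in-domain bins receive −G, fragmenting every domain. The
default here is therefore an **Otsu split** of the informative log-ratios
(maximizing between-class variance), which lands between the two modes
whenever they are separated, degrades to a median-like split on unimodal
input, and falls back to the median on degenerate (single-valued) input so
constant tracks yield zero enriched bins under the strict `>` rule.
`threshold_mode="median"` is available; the threshold used is always
recorded in the output.

**Blacklist semantics.** Bins overlapping the blacklist are
non-informative *and* act as hard segment breaks, so no call ever
intersects the blacklist. Bins with zero reference coverage are
non-informative but neutral (score 0): they may sit inside a call and are
what the informative-fraction threshold polices.

**Presets** ship for the four assay parameterizations used in practice
(gap penalty / bin size / fdr): SAMMY 25 / 50 kb / 0.05, H3K9me3
10 / 100 kb / 0.1, Lamin A/C 25 / 200 kb / 0.05, Lamin B1 5 / 100 kb /
0.05. The synthetic benchmark uses 10-kb bins with gap penalty 25, matched
to its genome and depth scale. Equivalence with the original EDD tool is
not claimed; what is demonstrated is recovery of planted truth and
internal error-rate calibration.

**Broad peaks** from a single mark use fixed windows (default 2 kb), a
window significant when its count z-score against the genome-wide Poisson
mean reaches the threshold (default 3), adjacent significant windows
merged.

## Overlap statistics

- **Jaccard index**: base-pair intersection over union of flattened sets.
- **Coverage fractions** are asymmetric: coverage of calls by a reference
  is the calls' precision; coverage of the reference by calls its
  sensitivity.
- **Shuffle test**: the chosen set is re-placed uniformly at random in the
  genome minus the blacklist N times (default 10,000), preserving interval
  lengths and count, optionally forbidding mutual overlap and optionally
  preserving chromosome assignment (shuffles may relocate intervals across
  chromosomes by default). Placement is sequential, longest first, uniform
  over all feasible start positions, so it fails only when the set
  genuinely does not fit. Empirical p uses the (k+1)/(N+1) estimator (never
  0; floor 1/(N+1)); the random mean ± SEM is reported.
- **Fisher overlap test**: the genome is tiled (default 10 kb) and bins
  cross-classified by overlap with each set; the 2×2 table is tested
  upper-tail (hypergeometric) and always returned for audit. The test
  assumes approximately independent bins: interval sets whose elements
  span many bins violate this and inflate significance, so bin size should
  be chosen at or above the interval scale.
- **Consensus/conservation**: consensus = bases covered by ≥ min_support
  sets (sweep-line); the conserved fraction of each sample is the share of
  its base pairs in the strict intersection of all samples.

## Metaprofiles

Border profiles sample a binned signal at ±K bins (default K = 50, 10-kb
bins) around each domain border. The window for a start border is centered
on the first bin inside the domain and for an end border on the last bin
inside — the two symmetric choices under the half-open convention — so the
domain interior lies at positive relative positions for starts and
negative for ends, and on a symmetric signal the start profile equals the
reversed end profile exactly. Windows extending past chromosome ends
contribute missing values excluded position-wise. Windows overlapping a
neighboring domain are included (a flag excludes them). The smoothed curve
is a cubic smoothing spline with GCV-chosen penalty applied to the
per-position means (and to mean ± 1.96·SEM for the band); the quantitative
surface is the unsmoothed means, the smoother is cosmetic. TSS profiles
use ±5 kb at 100-bp resolution (101 positions) with minus-strand windows
reversed. The common-peak TSS gene set intersects peak sets across all
samples and selects genes whose TSS ± 500 nt window touches a common
region by ≥ 1 bp.

## Kernel correlation

Both tracks are convolved per chromosome with a Gaussian kernel (default
SD 3 bins, reflective boundaries), mean-centered genome-wide, and
correlated bin-by-bin (SD 0 = plain Pearson). This defined estimator
preserves the meaning of kernel-correlation track comparison — tolerance
to spatially related but imperfectly overlapping features — without
claiming numerical equivalence to any external tool. Significance comes
from circular shifts of one track per chromosome by independent uniform
offsets, which preserve each chromosome's value multiset and
autocorrelation; z and the (k+1)/(N+1) one-tail empirical p are reported.

## Expression aggregation

Transcripts are assigned chromatin contexts from a labelled state
segmentation (Roadmap 15-state mnemonics): body states (Tx, TxWk, ReprPC,
ReprPCWk, Het, ZNF/Rpts) when ≥ 50% of the transcript body overlaps the
state; bivalent states (TssBiv, BivFlnk, EnhBiv) when the 200-nt window
centered on the TSS (TSS ± 100 nt) overlaps the state by ≥ 100 nt. A
transcript may carry several labels; an optional domain filter drops
transcripts whose body misses the filter set (e.g., restricting to genes
inside compaction domains).

Per group (× direction: up = positive signed effect, down = negative),
p-values are combined with the **Lancaster method**:
T = Σᵢ Q_Γ(wᵢ/2, scale 2; 1 − pᵢ), with T ~ χ²(Σ wᵢ) under the null.
Weights of 2 for every member recover Fisher's method exactly (verified
to 1e-10). The source weights used upstream are not recoverable, so the
default is equal weights (= Fisher) with a supplied-weights mode; the
choice is logged per run. p = 0 inputs are clamped at 1e-300 (the gamma
quantile diverges at 1). BH correction is applied across all rows of a
run; a cross-condition utility ranks groups by Σ(−log10 p). Bivalent
enrichment among hits uses a one-tail Fisher exact test on the 2×2 of
(hit × bivalent).

## Foci image analysis

Nuclei: global two-class Otsu threshold, holes filled, 8-connected
components, components < 200 px or touching the image border removed,
labels in raster order. Foci: per-nucleus three-class (two-threshold) Otsu
on the nucleus's intensities; pixels above the upper threshold are
candidates, provided that threshold exceeds the nucleus median by a
minimum relative contrast (default 0.5) — without this guard a uniform
interior is sliced into noise "foci". Components < 2 px are dropped;
nuclei < 10 px are skipped with a warning. Each focus's minimum distance
to the periphery is the exact Euclidean distance transform of the nucleus
mask minimized over the focus's pixels; the boundary point B is the
nearest background pixel realizing it (raster tie-break, affecting the
result by ≤ 1 px of geometry), and the size-independent **proximity** is
min_dist / ‖nucleus centroid − B‖, clamped to [0, 1] — 0 at the periphery,
1 at the centroid. The population summary reports cells / bodies / bodies
within a physical cutoff (default 1 µm) and the percentage.

## Synthetic data generator

The generator supplies every downstream stage with data of known truth.
It is a model of the *statistical structure* the analysis assumes, chosen
as the minimal construction that makes the pipeline's quantities
meaningful:

- **Architecture**: 2 chromosomes × 30 Mb with 10 planted non-overlapping
  closed-chromatin domains of 1–5 Mb placed uniformly at random —
  desk-scale, with chromosomes ≥ 10× the largest domain and domain sizes
  bracketing the megabase scale of real compaction domains.
- **Reads**: midpoints from a genome-wide multinomial whose per-base
  weight inside domains is the enrichment factor (default 3) for S4, its
  square root for S3 (the intermediate fraction's level is a free
  parameter), and its reciprocal for S2, 1 elsewhere. The S4/S2 in-domain
  density contrast is therefore factor² (= 9 at default). Sampling is
  stratified (exact): counts are multinomial across constant-weight
  strata, positions uniform within each stratum.
- **Disrupted condition**: with probability ρ (default 0.5) a read's
  domain bias is taken from a uniformly random re-placement of the
  domains, flattening and scattering the contrast without asserting a
  mechanism — reproducing, qualitatively, low signal-to-noise profiles
  whose domains differ between replicates.
- **Mark tracks**: ±1 square wave over the domains (majority rule per
  bin) plus Gaussian noise; +1 emulates lamina/heterochromatin marks, −1
  open/active marks.
- **State painting**: domains are chunked (50–200 kb) and labelled mostly
  Het/Quies with minority ReprPC/ReprPCWk and bivalent islands; outside is
  mostly Tx/TxWk/Quies. Every base carries exactly one label.
- **Transcripts**: bodies log-normally sized (median 20 kb), TSS at the
  5′ edge; null transcripts draw p ~ U(0,1] and symmetric effects;
  transcripts with a bivalent TSS window draw p ~ Beta(effect, 1)
  (default effect 0.2; 1 = global null) and positive effects with
  probability 0.8.
- **Nuclei**: one mildly elliptical nucleus per image (axis ratio
  0.85–1.0) with Gaussian foci at 5× the nuclear intensity; the focus
  radial position is drawn area-uniformly between 0.84·bias and 0.96, so
  bias = 1 confines foci to the outer shell (true proximity ≤ 0.2).
  Ground truth records exact boundary distances and proximities computed
  on the analytic ellipse.

What the generator does **not** model: sequence content and mappability
(no FASTQ, no GC or mappability bias), diploidy and copy number,
replicate correlation beyond independent seeds, fragment-length effects,
chromatin-state transition structure, non-elliptical nuclei, or
out-of-focus/3-D imaging effects. Passing tests therefore demonstrate the
correctness and calibration of the *methods* under the stated model —
they do not certify performance on real libraries, where these nuisances
are the hard part.

## Numerical and testing choices

- Every generator and every Monte-Carlo routine is a pure function of its
  arguments including an explicit seed; the full pipeline is
  byte-deterministic given its config.
- Empirical p-values always use (k+1)/(N+1), never 0.
- Problem sizes in the test-suite benchmarks (2 × 30 Mb genome, 1 M reads
  per fraction, 10-kb bins, 1000 permutations / shuffles, 2000
  transcripts, 50 nuclei) are the package's default study conditions,
  chosen so every property is testable on a workstation while keeping
  ≥ 100 bins per planted domain and ≥ 20 reads per bin.
- Ties at the polarity threshold are non-enriched (strict >); ties for
  the nearest boundary pixel break in raster order; the gap-penalty
  monotonicity property (higher G never increases called bp) is tested on
  a penalty ladder.

## Known limitations

- The permutation null exchanges bin scores genome-wide and therefore
  ignores residual spatial autocorrelation of counts within the null;
  at the tested depths this is conservative (null genomes yield zero
  calls at well below the nominal rate).
- The binned Fisher overlap test inherits the independence caveat above.
- No replicate-aware joint calling, no per-chromosome background, no
  automatic gap-penalty estimation.
- The foci pipeline is 2-D single-channel only.
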