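# Methods

## Coordinates and input handling

All coordinates are 0-based half-open internally. Bismark coverage positions
are treated as 1-based points and converted on read; writing converts back,
so round trips are exact. The beta value of a CpG is always recomputed as
methylated/(methylated+unmethylated) reads — the percent column on disk is
ignored. Sites below the coverage floor (default 10×, configurable) are
dropped; zero-coverage records are rejected with a warning. BED, narrowPeak
and bedGraph follow their usual half-open conventions; overlapping bedGraph
intervals are an error because the step-function value would be ambiguous,
while overlapping BED records are permitted. All readers accept gzip.

A gene's *promoter CGI* is a CGI containing at least one of its transcript
TSSs (point-in-half-open-interval). When several CGIs qualify, the CGI
containing the canonical (first-listed) TSS wins; remaining ties go to the
longest CGI, then the lexicographically smallest id. This tie-break is a
documented implementation choice — the underlying biology does not dictate
one — and several genes may legitimately share one CGI, each keeping its own
row in gene-level tables.

## Profile matrices

Promoter-CGI profiles are regions × bins matrices in
[upstream flank | scaled body | downstream flank] layout. The body is split
into n near-equal half-open bins (default 20; any bp remainder goes to the
leftmost bins), flanks are fixed-width (default 2 kb split into 20 bins per
side — chosen to match the TSS ± 2 kb promoter window used for mark
quantification, since no single flank width is canonical). Methylation bins
are *unweighted* means over the CpG sites in the bin (the convention of
enriched-heatmap-style tooling; read-weighting would couple bin values to
coverage fluctuations); histone bins are coverage-weighted means of the step
signal with uncovered positions counting as zero. Bins without data are
missing (NaN).

Gene-anchored analyses orient rows by strand, so bin 1 is always 5' of the
gene; this is what gives the C1/C2 labels their 5'/3' meaning. Raw
CGI-anchored heatmaps can disable orientation. Within-bin accumulation is
performed in a canonical (bin, value) order so that reversing both the
strand and the underlying signal reproduces a row bit-for-bit.

Clustering input must be complete: rows with more than 25% missing bins are
dropped (counted in a warning), the remaining gaps are filled by row-wise
linear interpolation over bin index with edge gaps taking the nearest
observed value. This policy is deterministic and logged; with the default
simulator geometry (CpG every 20 bp, bins ≥ 30 bp) it is rarely exercised.

## Accrual-mode classification

K-means uses Euclidean distance on the 20-bin Δβ (tumor − normal) profiles,
k = 5, greedy farthest-point seeding (first center drawn from the seeded
RNG), 10 restarts keeping the lowest within-cluster sum of squares,
convergence tolerance 1e-6, at most 300 Lloyd iterations. Centroids are
re-ordered by descending overall mean so cluster ids are canonical, and the
whole procedure is deterministic given the seed. An all-identical input is
accepted as a degenerate zero-inertia solution with a warning.

Cluster naming is a pure function of centroid geometry. With m the overall
centroid mean, m₅/m₃ the means of bins 1–10/11–20, t = `t_change` (default
0.10) and r = `asym_ratio` (default 2.0):

- C4 if m ≤ −t;
- C5 if |m|, |m₅|, |m₃| < t;
- otherwise hypermethylated: C1 if m₅ ≥ r·max(m₃, t/2), C2 if
  m₃ ≥ r·max(m₅, t/2), else C3.

The t/2 floor inside the max prevents a near-zero opposite half from
inflating the asymmetry ratio arbitrarily. Two centroids can in principle
earn the same name; they keep it, and the labeling reports the collision
rather than silently renaming — a k-means solution is not guaranteed to
realize all five verbal categories.

The WT/DKO classifier uses per-CGI unweighted mean beta over ≥10× CpGs
(CGIs with fewer than 3 covered CpGs fall to *other*): demethylation iff
β_WT ≥ 0.5 and β_DKO ≤ 0.2; unchanged iff both ≤ 0.2. The 0.5/0.2 cutoffs
operationalize "hypermethylated" and "unmethylated"; they are configurable
because no universal numeric definition exists.

## H3K4me1 patterns and the pre-mark comparison

Per-CGI H3K4me1 enrichment is the coverage-weighted mean over the CGI body
only (flanks excluded, so bimodal promoters with flanking peaks score low).
The high/low split is a 1-D two-means (Lloyd from min/max initialization,
threshold at the midpoint of the two final means, values at the threshold
going high); it is deterministic and fails loudly when all values are equal.

Shape calling reduces a flank/body row to: center mean (mean of the middle
50% of body bins) and two flank peaks (max over each flank plus the adjacent
outer quarter of the body). A row is *flat* when its overall max is below
`min_signal` (default 5% of the matrix-wide 95th percentile), *bimodal* when
both flank peaks reach `bimodal_ratio` (default 1.5) times the center mean,
otherwise *unimodal*. The call is scale-invariant above the floor. These
constants operationalize a visual dichotomy; all are configurable.

The pre-mark comparison reports per-group mean/median methylation gain, a
two-sided rank-sum p-value, the raw directional verdict (high mean gain
above low), and a `significant` flag (direction *and* p < α, default 0.01).
The raw direction alone is a coin flip under the null, so any claim that
H3K4me1 pre-marks hypermethylation is read from the significant flag.

## Statistics

- Tau: τ = Σ(1 − xᵢ/x_max)/(N − 1); log2(TPM+1) pre-transform on by default
  (the tspex convention), recorded in output metadata. Undefined for
  all-zero vectors or a single tissue.
- Spearman: Pearson correlation of mid-ranks (average ranks on ties),
  pairwise-complete; cells with fewer than 3 complete pairs are missing with
  a warning.
- Chi-square 2×2: closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), 1 d.f.,
  no Yates correction (large-sample use); zero marginals raise.
- Rank-sum: exact mode enumerates all C(n_a+n_b, n_a) label assignments on
  mid-ranks and doubles the smaller tail (capped at 1); used automatically
  for n_a+n_b ≤ 12, otherwise the tie-corrected normal approximation with
  continuity correction. Identical pooled values give p = 1.
- Hypergeometric enrichment: upper-tail P(X ≥ overlap) after intersecting
  each annotation set with the universe; fold =
  (overlap/|query|)/(|set|/|universe|); Benjamini–Hochberg q-values across
  sets.
- Domain assignment: majority overlap, PMD winning exact ties (the rarer,
  hypomethylation-context call), *other* when neither domain touches the
  region.

## The synthetic-data generator

One chromosome (`chrS`) carries n_genes (default 300) gene blocks at 6 kb
spacing, each with a promoter CGI (600–1400 bp) straddling its TSS and a
PMD-or-HMD background domain tiling the block. Defaults define the reference
study conditions:

- group fractions C1..C5 = 0.15/0.15/0.20/0.10/0.40 (largest-remainder exact
  allocation): C5 the largest group, C4 the smallest, matching the observed
  ordering of the groups in tumor methylomes;
- effect size δ = 0.3 beta; CGI baseline β = 0.05; HMD/PMD background
  β = 0.85/0.55; tumor adds δ to the 5' half (C1), 3' half (C2) or whole
  island (C3), and C4 promoters start partially methylated (β = 0.5) and
  lose δ in tumor — a loss of 0.3 from the common 0.05 baseline is
  impossible in [0, 1], so hypomethylation requires a methylated normal
  baseline by construction;
- CpGs every 20 bp inside CGIs and every 150 bp outside; read depth Poisson
  with mean 30× (min 1) and beta-binomial methylated counts with
  overdispersion ρ = 0.1, so the 10× filter retains >99% of sites while
  still being exercised;
- bivalent labels at 0.60 in C1–C3 vs 0.15 elsewhere; PMD placement at 0.30
  for hyper genes vs 0.06 otherwise — couplings chosen to reproduce the
  qualitative contrasts of tumor methylomes without claiming any measured
  effect size;
- H3K4me1: hyper-mode promoters high-unimodal (amplitude 8, Gaussian
  sd = L/5) in normal, scaled by 0.4 in tumor *on the same noise
  realization* (so the reduction is exact at zero noise); C4 low-unimodal
  (1.5); C5 bimodal, with flanking peaks placed just outside the island
  edges (±200 bp, sd 150 bp) and identical in both conditions. H3K4me3 is
  unimodal and condition-independent (independent noise per condition);
  H3K27me3 is elevated only at bivalent promoters. Multiplicative
  log-normal noise, σ = 0.1; peaks are emitted where binned signal exceeds
  1.0. `premark_coupling=False` shuffles the H3K4me1 classes across genes,
  giving the null used by the uncoupled seed suite;
- WT/DKO intents: demethylation probability 0.70 for bivalent genes vs 0.15
  otherwise (remainder mostly unchanged), WT betas 0.85/0.05/0.35 for
  demethylation/unchanged/other and DKO 0.03 everywhere;
- expression: 10 tissues; tissue-specific fraction 0.80 in hyper groups vs
  0.20 elsewhere with a 32-fold dominant tissue; hyper genes have a lower
  baseline (5 vs 50 TPM) and are down-regulated 0.3× in tumor; log-normal
  noise σ = 0.1.

Everything is deterministic given the config seed (each generator draws from
an independent child stream, so outputs do not depend on call order), and
identical configs produce byte-identical files.

What the simulator does *not* emulate: realistic CpG density and island
geometry, chromatin-state transitions, read-level sequencing artifacts,
copy-number effects, inter-sample heterogeneity, or genome-scale PMD
structure. Passing recovery tests therefore demonstrates that the estimators
are correct and well-calibrated under their own model assumptions — clean
planted effects with known noise — not that real tumor methylomes will
yield equally clean groups.

## Problem sizes and numerical choices

The reference dataset is 300 genes at 30× depth (≈25k CpG sites per
methylome); the pre-mark seed suites run 20 coupled plus 20 uncoupled
simulations at 120 genes each. These sizes put every planted contrast many
standard errors away from its null while keeping a full test-and-acceptance
run in the tens of seconds on one CPU. Tolerances used by the tests are
derived from the generating process (overdispersed-binomial standard errors
for methylation means, binomial bounds for planted fractions) rather than
tuned constants. Degenerate inputs have defined behavior throughout:
all-identical clustering input is accepted with a warning, an all-identical
enrichment vector refuses to split, empty comparison groups raise, and
promoter windows are truncated at the contig start with a warning.

## Known limitations

- The C1–C5 naming rule is an operationalization of verbal cluster
  descriptions; near-threshold centroids can flip names under small data
  perturbations even when the clustering itself is stable.
- The exact rank-sum enumeration is limited to n_a+n_b ≤ 12; beyond that the
  normal approximation (tie-corrected, continuity-corrected) is used, which
  is slightly conservative at very small n.
- Spearman cells are pairwise-complete, so different cells of one matrix may
  rest on different gene sets when missingness is uneven.
- The CLI consumes single-sample tracks per condition; replicate handling
  (e.g. averaging or consensus peak filtering) is upstream of this package.
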