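# cgimeth

Promoter CpG-island (CGI) DNA hypermethylation is an epigenetic hallmark of
cancer: tumors gain methylation focally at promoter CGIs — preferentially at
bivalent, developmentally regulated genes — while losing it globally across
partially methylated domains (PMDs). `cgimeth` is a tested, reusable Python
pipeline for analysing this dynamic from standard sequencing-derived inputs
(Bismark-coverage methylation calls, BED/bedGraph/narrowPeak annotations and
tracks, TPM expression tables). It is aimed at computational epigenomicists
who want the canonical promoter-CGI analyses as library functions with planted
ground-truth tests, rather than as one-off notebook code.

## What it computes

**Accrual-mode classification (C1–C5).** Each gene's promoter CGI (a CGI
containing at least one transcript TSS) is split into 20 strand-oriented bins
and the tumor-minus-normal beta difference Δβ is profiled per bin. K-means
(k = 5, Euclidean, best of 10 restarts) clusters the Δβ profiles, and
centroids are named from their geometry using the overall mean m and the
5'/3'-half means m₅, m₃:

- **C1** — 5' hypermethylation accrual (m₅ ≫ m₃),
- **C2** — 3' accrual (m₃ ≫ m₅),
- **C3** — island-wide hypermethylation (m ≥ t, symmetric),
- **C4** — hypomethylation (m ≤ −t),
- **C5** — unchanged (|m|, |m₅|, |m₃| < t),

with threshold t = 0.10 and asymmetry ratio 2.0 by default. C1–C3 together
form the *all-hyper* group.

**H3K4me1 pre-mark analysis.** Promoter H3K4me1 occurs either as a single
central peak (unimodal, poised promoters) or as two flanking peaks with a
central dip (bimodal, active promoters). The pipeline calls these shapes from
flank/body profile rows, splits promoter CGIs into H3K4me1-high/low classes
by 1-D two-means on normal-tissue enrichment, and tests whether the high
class gains more DNA methylation in tumor (Wilcoxon rank-sum) — i.e. whether
normal-tissue H3K4me1 *pre-marks* tumor hypermethylation.

**WT/DKO demethylation groups.** In DNMT1/DNMT3B double-knockout (DKO) cells,
promoter CGIs are classified from mean beta values as *demethylation*
(β_WT ≥ 0.5 and β_DKO ≤ 0.2), *unchanged* (both ≤ 0.2) or *other*.

**Associated statistics.** Tau tissue-specificity index
τ = Σᵢ(1 − xᵢ/x_max)/(N − 1) on TPM vectors; Spearman correlation matrices;
2×2 chi-square (closed form, no continuity correction); exact and
tie-corrected asymptotic rank-sum tests; hypergeometric set enrichment with
Benjamini–Hochberg q-values; upset-style exclusive overlap counts; PMD/HMD
majority-overlap assignment; and the ChIP-qPCR conversion
%input = 100 · f_input · 2^(CT_input − CT_sample).

**Synthetic data.** A first-class simulator builds a miniature chromosome
with all of the planted structure above (accrual modes, bivalent labels,
PMD/HMD tiling, coupled H3K4me1 shapes, WT/DKO intents, tissue-specific
expression), samples CpG read counts beta-binomially, and emits both the
ground truth and every file format the readers accept — so the entire
pipeline is testable end-to-end without external downloads.

## Worked example

```python
from cgimeth.simulate import SimulationConfig, simulate_dataset
from cgimeth import pipeline

ds = simulate_dataset(SimulationConfig(n_genes=200, seed=11))
assignments = pipeline.classify_dataset(ds)
print(assignments["label"].value_counts().sort_index())

premark = pipeline.premark_dataset(ds)
print(f"high-H3K4me1 gain: {premark['high_mean']:+.3f}  "
      f"low: {premark['low_mean']:+.3f}  p = {premark['p_value']:.2e}")
```

prints

```
label
C1    30
C2    30
C3    40
C4    20
C5    80
Name: count, dtype: int64
high-H3K4me1 gain: +0.209  low: -0.063  p = 2.56e-34
```

The five counts exactly match the planted group fractions (0.15/0.15/0.20/
0.10/0.40 of 200 genes), and the pre-mark comparison shows that promoter
CGIs with high normal-tissue H3K4me1 gained ≈0.21 mean beta in the tumor
methylome while the low class did not — the planted coupling, recovered with
an overwhelmingly significant rank-sum p-value.

The same analyses run from the shell on files:

```sh
cgimeth simulate --n-genes 200 --seed 11 --outdir sim
cgimeth classify --normal-meth sim/normal.cov --tumor-meth sim/tumor.cov \
    --cgi-bed sim/cgis.bed --genes sim/genes.tsv --bivalent sim/bivalent.tsv \
    --pmd-bed sim/pmds.bed --hmd-bed sim/hmds.bed \
    --expression sim/expression_tissues.tsv --seed 11 --outdir out
```

`out/` then contains tidy TSV tables (assignments, Tau, domain fractions),
a `summary.json` with the chi-square and rank-sum results plus a full
config/provenance echo, and a run log listing any skipped optional sections.

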