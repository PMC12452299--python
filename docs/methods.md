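# Methods

## The analytical model

The package treats an XIST/Xist-loss experiment as three nested questions.

**Chromosome level.** Is the X chromosome's share of differentially
expressed genes unusual? A gene is a DEG when `padj < 0.05` and
`log2FC > 0.58` (up) or `< −0.58` (down); both inequalities are strict, and
a missing `padj` never qualifies (the conservative reading of NA semantics
in count-based DE tools). The 0.58 log2 threshold is used rather than the
rounded linear 1.5× (2^0.58 ≈ 1.495); the two differ only at the fourth
decimal of the fold change. Percentages divide by the chromosome's
annotated gene count — the annotation file supplied to a run is treated as
authoritative for that denominator, and each run logs how many DE genes
failed to map into it. Ranks descend; ties break by karyotype name order so
results are deterministic. The Y chromosome and unplaced scaffolds are
excluded, making the ranking universe 23 chromosomes for human annotations
and 20 for mouse. The Z test on pooled counts (X vs summed autosomes,
top-ranked vs summed rest) uses the pooled-variance two-proportion
statistic, whose square is the uncorrected chi-square of the 2×2 — a test
identity the suite asserts. A degenerate pooled proportion (0 or 1) carries
no evidence and is reported as z = 0, p = 1, flagged.

**Distribution level.** Rank statistics on DEG counts discard most of the
signal, so fold-change distributions are compared directly: two-sample
two-sided Kolmogorov–Smirnov tests of X vs pooled autosomes, control
autosome vs autosomes, and X vs control. The control autosome is chosen as
the autosome whose gene count is nearest the X's (chr9 for human, chr10 for
mouse annotations), ties toward the earlier name. The comparison universe
is every gene with a non-missing log2 fold change; an expressed-only
restriction (e.g. mean FPKM ≥ 1, threshold inclusive) is available where a
dataset calls for it. A shift is directional only when the KS test is
significant at 0.05 and the median difference agrees; the three pairwise
tests are reported without multiplicity correction, as they answer three
separate questions. No correction is applied across datasets either.

**Gene level.** Allele-specific expression distinguishes reactivation of
the inactive X from overall upregulation. The per-SNP allelic ratio
`AR = min(ref, alt)/(ref + alt)` folds the minor allele below 0.5 and needs
at least 10 reads to be informative. Per-gene AR is the total-read-weighted
mean of per-SNP ARs: pooling folded counts across SNPs first would read two
oppositely skewed SNPs (30/10 and 10/30) as perfectly biallelic, so count
pooling (`sum_counts`) exists only as an explicit alternative, and the two
are worth comparing whenever phasing is unavailable. A gene's change class
demands concordance: `up` only if AR rose in *every* knockdown clone,
`down` only if it fell in every clone; an exact tie in any clone is
`discordant` (increase must be strict), and any missing AR makes the gene
`incomplete`. Only concordant escape/inactive genes enter the 2×2
contingency table; Fisher's exact two-sided p sums hypergeometric outcomes
no more likely than the observed table (the minimum-likelihood convention,
matched to brute-force enumeration in the tests), alongside the
unconditional sample odds ratio ad/bc (undefined, reported as NaN, when
b·c = 0). ΔAR distributions of escape vs inactive genes are compared with
Mann–Whitney U (exact for ≤ 8 per group without ties, tie-corrected normal
otherwise); Shapiro–Wilk normality p values are reported per group but
never gate the rank test.

**Spatial level.** DEG positions are the interval midpoints
`⌊(start+end)/2⌋`. Densities along a chromosome use 1 Mbp windows advanced
by 250 kbp; only full windows are kept (constant denominator), except that
a chromosome shorter than one window yields a single truncated window.
Count mode places features by midpoint (each midpoint lands in up to
window/step overlapping windows); coverage mode divides overlapped base
pairs by the window size and is offered for repeats, whose "density" is
ambiguous between the two readings — count is the symmetric default for
every feature class. Pearson r between tracks gets its p from the t
distribution with n − 2 df; the first-order partial correlation of DEG and
SINE density given gene density uses the closed form with n − 3 df and is
verified against the residual-regression definition to 1e-10. Because the
windows overlap fourfold, neighboring values are autocorrelated and the
nominal p values are optimistic; they are comparable across datasets
computed on the same grid, which is how they are used.

## Coordinates and I/O

All intervals are 0-based half-open internally; GTF (1-based inclusive) and
RepeatMasker `.out` coordinates are converted at the I/O boundary and
restored on write, so round trips are exact. Chromosome names are
normalized to the `chr` prefix. Gene length for TPM/FPKM is the union of
exon intervals when the GTF carries exons, an explicit length
attribute/column when present, else `end − start`. TPM columns sum to 1e6
by construction; FPKM is `1e9 · c/(L·N)`. DE tables are ingested in the
column dialect of count-based DE tools and never recomputed for real data.

## The minimal DE test

For synthetic counts only, the package fits a deliberately minimal
negative-binomial Wald test: median-of-ratios size factors (genes with any
zero excluded from the geometric-mean reference; a positive-count
pseudo-reference behind an explicit flag), a per-gene method-of-moments
dispersion replaced by a fitted trend `α(μ) = a₀ + a₁/μ` (weighted least
squares with one trimming pass, floored at 1e-8), a pseudocounted
(`+0.5`) log2 fold change, and a delta-method Wald z with two-sided normal
p, BH-adjusted. The trend replaces raw per-gene moments because at 3 vs 3
replicates the per-gene estimate is too noisy to keep the null type-I rate
near α; with the trend the simulated-null false-positive rate sits at
0.04–0.05. There is deliberately no shrinkage, no independent filtering and
no covariate handling — real datasets should arrive as DE tables from a
dedicated tool.

## What the generator emulates

* **Genome.** 22 autosomes of 100 Mbp plus a 155 Mbp X (all configurable);
  gene counts scale with chromosome length, 217 per 100 Mbp by default so
  the default genome has ~5,100 genes — a deliberately scaled-down genome
  that keeps a full run in seconds while preserving per-chromosome gene
  counts large enough for stable percentages. One X-linked gene near the
  73.8 Mbp position is named XIST and knocked down to 8% of its control
  mean in deficient samples (a >90% reduction, as achieved by typical
  knockdowns).
* **Spatial structure.** Each chromosome carries a latent Gaussian field on
  250 kbp bins, smoothed with a 500 kbp kernel and exponentiated, giving
  gene clusters at the megabase scale. SINE and LINE fields share the gene
  field through a Gaussian copula. The latent correlation is calibrated
  analytically so the *realized window-count* correlation hits the target:
  the lognormal transform is inverted exactly, and the Poisson sampling
  attenuation (variance share `λ·(e^{σ²}−1)·m/(λ·(e^{σ²}−1)·m + 1)`, with
  m the mean within-window bin correlation) is divided out. Negative
  lognormal correlations are bounded away from −1; an infeasible target
  triggers a warning carrying the achievable value. Defaults
  (ρ_gene–SINE = 0.6, ρ_gene–LINE = −0.4, gene σ = 0.7, LINE σ = 0.5) are
  feasible and recover to within sampling noise; a single ~600-window
  chromosome measures r with a standard error near 0.08, so recovery checks
  average a handful of seeds.
* **Counts.** NB with lognormal means (median ≈ 110, log-sd 1.2, about 1.1
  million reads per sample), dispersion trend `0.05 + 2/μ` with 20%
  lognormal gene-to-gene noise, and lognormal size factors (sd 0.15).
  Scenarios: `stem` upregulates `round(f_x · n_X)` X-linked genes (default
  f_x = 0.15) by δ = 1 log2 unit; `differentiated` affects the same number
  of genes placed genome-uniformly; `null` affects none.
* **Allelic counts.** Minor-allele fraction 0.02 for inactive, 0.25 for
  escape genes (between for `variable`); 3 SNPs per gene at 60 reads per
  SNP, 60% of X genes informative. Knockdown shifts p by +0.2 for a
  reactivated subset and −0.2 for a monoallelized subset, identically in
  both clones, clamped into [0, 0.5]. AR truth works directly on the minor
  fraction, so no phase bookkeeping is needed.
* **Determinism.** Every stage draws its RNG from `(seed, stage)`, so a
  stage can be regenerated without rerunning the ones before it and a full
  bundle is byte-identical under a fixed seed.

What it does **not** emulate: realistic karyotypes and gene-count
asymmetries between chromosomes (the control-chromosome choice degenerates
to a name-order tie-break), repeat subfamily structure, library-preparation
biases, correlated genes (co-expression), allelic mapping bias, or X
erosion dynamics. Tests passing on this generator therefore demonstrate
that the statistics recover the structure they are defined on — not that
any particular biological dataset will show that structure.

## Numerical choices and degenerate inputs

Pseudocount 0.5 in the synthetic log2 fold change (configurable); BH over
non-missing p only, NaN propagated; all-zero genes get missing p/padj and
class `none`; all-zero samples make TPM undefined and raise; a WT FPKM of
zero skips that replicate pair with a warning (all pairs skipped → missing
fold change); constant vectors make Pearson undefined and raise; a control
correlation of ±1 makes the partial correlation undefined and raises.
Window grids must match exactly for cross-dataset correlation — the error
suggests re-running with shared window/step. Unknown XCI labels map to
`unknown` with a warning and are excluded from the contingency analysis.

## Problem sizes used by the checks

The acceptance script runs the default ~5,100-gene genome for scenario
discrimination, 200 null replicates for calibration (KS rejection rate and
DE type-I), five single-chromosome genomes (617 windows each) for density
coupling recovery, and three allelic simulations (~200 informative genes
each); the whole script completes in a few seconds on one core, and the
full pytest suite in well under a minute.
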