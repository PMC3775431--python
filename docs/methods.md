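# Methods

This note documents the statistical models, algorithms, defaults and design
choices behind `plasmodebench`, and what its synthetic fixtures do and do
not establish about real data.

## The simulation model

Counts are generated from a hierarchical (lognormal-Poisson) model: for
transcript g, treatment group i ∈ {1, 2}, biological replicate j and
technical replicate k,

    y_gijk ~ Poisson(λ_gijk),
    log λ_gijk = O_ijk + μ_gi + e_gij,     e_gij ~ N(0, σ²_g).

* `O_ijk` is the known natural-log library size of the column (the offset).
* `μ_gi` is the group mean on the log fraction-of-library scale (a gene with
  μ = log(50·10⁻⁶) averages 50 counts per million reads).
* `e_gij` is drawn **once per biological sample** and shared by its r
  technical columns; technical replication therefore adds sequencing depth
  but no independent biological variation. Marginally the counts are
  over-dispersed Poisson with Var = m + (e^{σ²} − 1)·m², which is *not* a
  negative binomial — deliberate, so the NB engines are never tested on
  data drawn from their own family.

A dataset is a T × 2nr matrix. Exactly ⌊p₀·T⌋ transcripts are assigned to
S₁ and keep their sampled group means (true log effect μ₂ − μ₁); the rest
form S₀ with both means replaced by their average, preserving each gene's
overall abundance. The fixed count (rather than Bernoulli-per-gene
assignment) pins the S₀/S₁ denominators used by evaluation. The scenario
grid crosses n ∈ {3, 5, 10} with r ∈ {1, 3, 5} (9 cells, K datasets each),
with p₀ = 0.1 by default; each cell uses its own sub-seed spawned from the
master seed, so a (seed, config) pair determines every count.

**Offsets.** Library sizes default to lognormal with mean 2·10⁷ reads and
CV 0.2 (`offset_scheme` configurable, `equal` available). A log-rate above
700 raises an error naming the gene rather than silently saturating.

## Parameter estimation (moment matching)

The per-transcript parameters feeding the simulator are estimated from a
real or synthetic dataset by closed-form moment matching rather than by a
Poisson GLMM fit: with depth-corrected rates z_j = y_j / e^{O_j} in group i,

    m̂_i = mean(z_j),
    v̂_i = max(0, var(z_j) − m̂_i · mean(e^{−O_j}))        (excess variance),
    σ̂²  = log(1 + Σ_i n_i v̂_i / Σ_i n_i m̂_i²),
    μ̂_i = log(m̂_i) − σ̂²/2.

This is exact for the generating model (the Poisson shot-noise term is
subtracted before matching the lognormal variance inflation) and
dependency-free; only the induced distribution of (μ, σ²) matters for
benchmarking. Genes with a zero mean rate in any group are dropped (their
log mean is undefined); each group needs ≥ 2 biological replicates.
Recovery at n = 200 per group is within ~0.01 of truth for both μ and σ²
(the acceptance script reports the realized errors).

## Plasmode construction

*Null plasmodes* (exchangeable base, no structure): each of p datasets
draws t·r distinct base columns uniformly without replacement, copies them
**unchanged**, and labels the first r as group 1, the next r as group 2.
Every gene is truly null; the per-gene joint distribution and gene–gene
correlation of the base data are preserved exactly. Defaults follow the
21-sample human B-cell archetype: p = 10, t = 2, r = 10 (one sample unused
per plasmode, drawn independently each time).

*DE plasmodes* (two-treatment, blocked base): per plasmode,

1. samples are randomly partitioned into two pseudo-treatment groups
   **within each block**, sizes as equal as possible (odd block sizes
   alternate the larger side across blocks); every admissible balanced
   partition is equally likely;
2. round(π·T) genes are selected uniformly (π = 0.20 by default) and each
   receives a natural-log effect β. In the default `sampled_from_G` mode the
   βs are drawn with replacement from the effect set G; in
   `own_effect_G_only` the spiked genes are themselves drawn from G and keep
   their own estimates (both readings of "add effects estimated from real
   data" are supported because the intent is genuinely ambiguous);
3. the effect is imposed by **binomial thinning**: counts of the
   pseudo-group on the down side of β are replaced by Binomial(y, e^{−|β|})
   draws. Thinning keeps counts integer and preserves count mean–variance
   behavior, unlike multiply-and-round; thinned values never exceed the
   originals, and β = 0 or an all-zero row are exact no-ops.

The effect set G is selected by the package's own NB-LRT engine
(treatment + block, tagwise dispersions) with Benjamini–Hochberg q ≤ 0.01
by default ("sufficiently small" is the only hard requirement; 0.01 keeps G
high-confidence). BH is the only multiple-testing correction anywhere in the
package, and it is used only here.

## Testing engines

All engines consume a filtered count matrix (below) and a nested
full/reduced fixed-effect model (treatment, optionally + block) with
treatment-contrast coding, first-appearing level as reference.

**NB GLM + LRT.** Per gene, a negative binomial GLM with log link and fixed
dispersion φ (Var = μ + φμ²) is fitted by IRLS, vectorized across genes;
φ = 0 degenerates to the Poisson GLM. Convergence: relative deviance change
< 10⁻⁸ or 50 iterations; non-convergence flags the gene (p missing,
excluded downstream) rather than raising. The LRT statistic is the deviance
drop from reduced to full model, referred to χ² with df = rank difference.

Dispersion policies:

* `common` — one φ maximizing the summed Cox–Reid adjusted profile
  log-likelihood (APL: profile log-likelihood minus ½ log det X'WX) over a
  21-point log-spaced grid on [10⁻⁶, 10], refined by parabolic
  interpolation.
* `tagwise_shrunk` — per-gene maximizer of APL_g(φ) + w₀·ĀPL(φ), where ĀPL
  is the across-gene average APL and w₀ = 10 gene-equivalents (the classic
  prior weight of empirical-Bayes tagwise estimation; configurable). Offsets
  come from TMM effective library sizes.
* `trend_max` — per-gene method-of-moments estimate on size-factor
  normalized counts, pooled across design cells,
  φ̂_g = max(0, (s²_g − ȳ_g)/ȳ_g²); a trend φ(μ) = a₀ + a₁/μ fitted by least
  squares over genes with φ̂ > 0; final φ_g = max(φ̂_g, φ(ȳ_g)). This is the
  conservative "take the maximum" sharing rule. Offsets come from
  median-of-ratios size factors.

**Gaussian engines.** On log2-CPM values, per-gene OLS under the same
full/reduced pair gives F1 = ((RSS_r − RSS_f)/df_num)/(RSS_f/df_res). The
moderated Fs replaces the per-gene residual variance by a shrunken value:
with Z_g = ln σ̂²_g and V = trigamma(df_res/2) (the sampling variance of the
log of a scaled χ²), each Z is pulled toward the mean by the positive-part
James–Stein factor (1 − (G − 3)·V/Σ(Z − Z̄)²)₊ and exponentiated. When all
variances are equal, or G = 3, Fs coincides with F1.

p-values: *tabulated* — upper tail of F(df_num, df_res) for F1 and Fs alike
(moderation changes the statistic, not the reference); *permutation* —
treatment labels are shuffled (within blocks on blocked designs, respecting
the restricted randomization), the statistic recomputed for all genes, and
the null pool formed from **all genes × all permutations** (100 by
default). p_g = (1 + #{null ≥ observed_g}) / (1 + pool size); the add-one
rule means permutation p-values are never exactly zero, and their
granularity is 1/(1 + pool size). When fewer distinct label arrangements
exist than requested, the space is enumerated exhaustively (for two-group
designs an arrangement and its global label swap are counted once, since
they give identical statistics).

## Filtering, normalization, transformation

* Technical replicates are summed into their biological sample before
  anything else (they represent depth only).
* Filter: keep genes with ≥ 2 reads per million in at least n_bio libraries
  (n_bio = biological replicates per group), computed on raw library sizes
  before any normalization.
* TMM scale factors: reference column = the one whose 75th-percentile
  depth-scaled count is closest to the mean of those percentiles; genes
  zero in either column excluded; 30% trim on log-ratios M, 5% on average
  log abundance A (tails split equally); inverse-variance precision weights;
  factors rescaled to geometric mean 1. Verified against an independent
  reference implementation to 10⁻⁶ on a seeded matrix.
* Median-of-ratios size factors: s_j = median over genes positive in every
  sample of y_gj / (∏_k y_gk)^{1/m}.
* log2-CPM: x = log2((y + 0.5)/(effective library size + 1)·10⁶); the prior
  count and the +1 keep the transform finite for all nonnegative counts.
  No precision (mean–variance) weighting is applied: the Gaussian engines
  consume the transformed values directly.

## Evaluation conventions

Declaration is inclusive (p ≤ α), which keeps permutation-granularity
points on the curves. Empirical type-I error is the false positive rate
over S₀ genes; the default nominal grid is 30 log-spaced points on
[10⁻⁴, 10⁻¹], covering the region where count-model miscalibration
concentrates. ROC thresholds default to all distinct p-values ∪ {0, 1}
(a fixed grid is also supported). Q-Q data replace zero p-values by the
minimum positive observed p-value before taking −log10 (relevant for
engine-agnostic input; the in-package permutation engine cannot produce
zeros). Genes with missing p-values are dropped from both results and
truth, with the count recorded. Curve aggregation across K datasets keeps
every individual curve — the spread across plasmodes is itself a finding —
plus a pointwise mean by interpolation onto the union of thresholds.

## Synthetic fixtures: what they emulate, what they don't

`cheung-like` emulates a structureless experiment: 5000 genes × 21
exchangeable samples, NB counts with gene-level log-means ~ N(log 50 CPM,
1.5²), gamma-distributed dispersions (shape 2, mean 0.15), lognormal
library sizes (mean 5·10⁶, CV 0.3). `bottomly-like` adds two treatment
groups of 10 + 11 samples interleaved across 3 blocks, a planted effect on
10% of genes (magnitude uniform on [ln 2, ln 8], random sign) and
per-(gene, block) log shifts with SD 0.3 emulating a strong flowcell
effect. The default parameter pool draws μ₁ ~ N(log 50 CPM, 1.5²), effects
δ ~ ½N(0, 0.5²) + ½N(0, 1²) and σ² ~ Gamma(shape 2, mean 0.1).

These are declared, versioned distributions — **not** fits to any real
dataset. Passing tests on them establishes the machinery (bookkeeping,
calibration under the stated models, oracle agreement), not that any engine
is well- or mis-calibrated on a particular real experiment; real base
tables can be loaded through `io_tables` and run through the identical
pipeline. Known omissions: no gene–gene correlation in the parametric
fixtures (plasmodes from real bases exist precisely to supply it), no gene
length or GC effects, no read-level artifacts.

## Numerical choices and degenerate inputs

* IRLS adds a 10⁻¹⁰-scaled ridge to X'WX so genes with an all-zero group
  remain solvable (their fitted group mean collapses toward zero).
* Dispersion grid range [10⁻⁶, 10]; estimates at the lower boundary mean
  "Poisson-like".
* Fractional counts are rejected, never rounded, so thinning/spiking
  decisions stay explicit; all writers serialize floats with 12 significant
  digits for reproducible round trips.
* An empty effect set G is a warning (a legitimate outcome of a strict
  q-threshold), but asking for DE plasmodes with an empty G is an error.
* Chi-square/normal approximations are never used for permutation p-values;
  exhaustive enumeration takes over automatically for small designs.

## Problem sizes

The test suite and the acceptance script run everything at sizes chosen to
make the statistical assertions sharp but cheap: the scaled-down
replication of the type-I-error comparison uses K = 50 datasets of
T = 2000 transcripts at the least-replicated scenario (n = 3, r = 1),
giving ~90 000 pooled null genes per engine — ample to resolve a 3–5×
inflation at α = 0.001 — and completes in well under a minute on one CPU.
Full-size runs (K = 1000, T = 5000) are a `RunConfig` change away and scale
linearly.
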