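# Methods

## Scope and assumptions

mrkit implements summary-data two-sample Mendelian randomization: all
inference uses per-variant effect estimates (beta, SE) from two separate
GWAS, never individual-level genotypes. The usual two-sample assumptions
apply throughout: non-overlapping samples drawn from one ancestry, effects
on the log-odds (binary traits) or linear scale, and instruments satisfying
relevance, independence from confounders, and the exclusion restriction —
with the diagnostics below probing the third.

## Harmonization

Variants are matched by identifier only (rsID or chr:pos:ref:alt); no
positional fallback is attempted because both-the-same-key matching is the
norm for the curated repositories this data comes from. An outcome record
whose alleles are swapped relative to the exposure has its beta negated and
its allele frequency complemented. Strand (complement-base) rescue is
deliberately not attempted: complement-coded non-palindromic records are
dropped as mismatches, which is conservative and consistent with removing
palindromic variants. Palindromic variants (A/T, C/G) are dropped by
default; an opt-in relaxation retains those whose allele frequencies on both
sides are informative (farther than `palindromic_eaf_window = 0.08` from
0.5) and orients them by frequency concordance. Every removal is logged
with its reason, so retained + dropped always equals the ID intersection.

## Instrument selection

Three filters in sequence, each with its field-standard default:
significance p < 5×10⁻⁸ (strict inequality), greedy LD clumping
(window 10,000 kb, prune r² > 0.001, index priority by p-value with
variant-ID tie-break for determinism), and per-variant strength
F = β²/SE² > 10. LD is an explicit input — a pairwise r² table/matrix or a
declared "independent" panel — so selection is reproducible without a
genotype reference; an unknown r² for a same-window pair is treated as
linked by default (conservative) or can be made an error.

## Estimators

All confidence intervals are normal-theory at 95%; odds ratios are
exponentiated log-odds at the reporting boundary only.

* **IVW.** Weighted origin regression; closed form. Random effects uses
  multiplicative overdispersion, SE × √max(Q/(n−1), 1) — the dominant
  convention in two-sample MR software; the floor at 1 prevents
  under-dispersion from shrinking the SE. The `auto` model applies the
  heterogeneity-gated rule (random iff Q p < 0.05) and records which branch
  fired, because analyses in this field report that choice.
* **MR-Egger.** WLS with intercept on sign-oriented effects
  (β_X ≥ 0); covariance scaled by max(RSS_w/(n−2), 1), same floor logic.
  The intercept, its SE and p constitute the directional-pleiotropy test.
  Note the orientation step makes Egger sensitive to sub-significance
  instruments whose observed exposure effect can flip sign; the estimator
  is meant to run on selected (F > 10) instruments, where flip probability
  is negligible.
* **Weighted median.** Percentile construction p_j = (S_j − w_j/2)/ΣW over
  ratio-ordered instruments, linear interpolation at 0.5, first-order ratio
  weights β²_X/se²_Y. SE by parametric bootstrap (default 1,000 resamples,
  seed mandatory, default 0): per-SNP effects are redrawn from their
  sampling normals and the estimator re-applied.
* **Weighted mode.** Normal-kernel weighted density over ratios; bandwidth
  phi × 0.9 × MAD_sd × n^(−1/5) (MAD scaled by 1.4826; SD fallback for
  degenerate MAD), evaluated on a fixed 10,000-point grid spanning the
  ratio range ± 3 bandwidths; argmax is the estimate. The bootstrap reuses
  a 2,000-point grid for speed; grid sizes are parameters. phi defaults
  to 1.
* **Wald ratio.** Single-instrument fallback, first-order SE |se_Y/β_X|
  (exposure-side uncertainty ignored, standard at F > 10).

## Diagnostics

Cochran's Q uses first-order ratio weights; under the null of homogeneity
with known outcome SEs it is exactly χ²(n−1) in the simulator's model. The
regression-form equivalent is implicit in the IVW origin fit (the two agree
algebraically). Leave-one-out refits the heterogeneity-gated IVW n times
and flags exclusions whose CI lands on the opposite side of zero from the
full-set estimate. Funnel data pairs each ratio with its precision plus the
IVW/Egger reference-line parameters.

MR-PRESSO follows the simulation framework: observed residual sum of
squares from leave-one-out IVW slopes, compared against parametric
replicates (default 1,000) drawn from the no-pleiotropy model; per-SNP
outlier p-values from each SNP's own simulated residual distribution,
Bonferroni-adjusted at α = 0.05; a distortion test comparing the
raw-vs-corrected difference against random same-size removals (default
1,000 draws). Empirical p-values use the permutation convention
(count + 1)/(n_sim + 1) so they stay in (0, 1]; with the default 1,000
simulations the smallest achievable Bonferroni-adjusted outlier p is
n/(1,001), so panels larger than ~50 instruments need proportionally more
simulations to flag anything at 0.05. Simulation order is canonicalized by
variant ID, making results independent of input row order for a fixed seed.
The corrected estimate is exactly the gated IVW refit on the non-flagged
subset.

## Multivariable MR

Instruments are the union of each exposure's genome-wide-significant
variants, clumped jointly with each variant's best (minimum) p across
exposures as its index priority — union rather than intersection maximizes
identification and is standard practice. All datasets are aligned to the
first exposure's allele frame. The fit is WLS of outcome effects on the
exposure-effect matrix without intercept, weights se_out⁻², fixed-effects
covariance (X′WX)⁻¹ by default; Q-based multiplicative scaling is exposed
as an option but off by default. Exact collinearity raises an error naming
the involved exposures; a mean marginal F < 10 for any exposure triggers a
weak-instrument warning rather than an error, since conditional instrument
strength is out of scope.

## Mediation

Two-step decomposition on the log-odds scale: IE = β₁β₂ with first-order
(Sobel) variance β₂²σ₁² + β₁²σ₂² — the second-order σ₁²σ₂² term is omitted,
matching the cited-literature standard for the delta method; DE = TE − IE
holds by construction. The mediated proportion IE/TE uses the ratio delta
method with the three estimates treated as independent, justified by their
provenance from non-overlapping GWAS. A zero TE leaves IE and DE defined
but the proportion NaN with a warning.

The screen applies Benjamini–Hochberg step-up q-values to step-1 p-values
across the whole panel (q < α, default 0.05); step-2 survivors are tested
at unadjusted p < α (configurable separately) using the mediator's own
instruments, mirroring how such screens are reported. Mediators with no
usable instruments or no overlap are flagged and skipped, never fatal.

## Synthetic data

The generator emulates large-biobank summary statistics. Per variant:
MAF ~ U(0.05, 0.5); true per-allele effect half-normal with scale 0.02;
SE = 1/√(2·maf(1−maf)·n), coupling frequency, sample size and power with a
single parameter; observed effects are truth plus normal noise at that SE;
p-values are Wald. Default sample sizes are 400,000 for the exposure and
outcome GWAS and 115,000 for mediator GWAS, matching the biobank-scale
disease GWAS and NMR-metabolite panels this package targets; with those
defaults, selected instruments carry F ≈ 30–100, as in such studies. The
half-normal (positive) orientation of true effects makes "directional"
pleiotropy well defined.

Pleiotropy regimes on a configurable invalid fraction: balanced (zero-mean
normal direct effects), directional (non-zero mean; biases IVW, detectable
by Egger since InSIDE holds), and correlated (direct effects proportional
to instrument strength; violates InSIDE, degrading Egger and favoring
median/mode). Gross outliers add a configurable multiple (default 10) of
the outcome SE. The mediation chain gives the exposure's instruments slope
β₁ on the mediator and DE + β₁β₂ on the outcome, and gives the mediator its
own instruments with slope β₂ on the outcome, so the implied total effect
is DE + IE by construction. Variants are unlinked by default (spaced
outside the clumping window); optional LD blocks exist solely to exercise
clumping.

What the simulator does **not** model: sample overlap between the two GWAS,
LD beyond the rectangular block toy structure, allele-frequency differences
between cohorts, strand errors, winner's-curse in the discovery GWAS, and
binary-trait liability-scale subtleties. Passing tests therefore establish
correctness of the estimators and their calibration under the stated
sampling model, not robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

p-values are floored at the smallest positive double to honour the (0, 1]
contract. A zero exposure effect makes the Wald ratio undefined and raises;
bootstrap draws that hit exactly zero are nudged by machine epsilon.
Estimators raise structured errors below their minimum instrument counts
(IVW 2, Egger/median/mode 3, MR-PRESSO 4) rather than returning degenerate
numbers; the pipeline falls back to the Wald ratio for single-instrument
sets. Clumping ties are broken lexicographically by variant ID. All
stochastic components (bootstraps, MR-PRESSO, the simulator) take explicit
seeds and are bit-reproducible; pipeline reports regenerate identically
from the same config and inputs.

## Test problem sizes

The statistical acceptance suite uses 500-replicate Monte-Carlo families
for calibration and recovery checks (100-SNP panels; 200 SNPs for
multivariable MR), 100 replicates for the MR-PRESSO detection rates, and
four 249-mediator null panels for FDR behaviour of the screen; recovery
assertions use 3–4 σ Monte-Carlo tolerances computed from the replicate
spread itself. These sizes give per-check Monte-Carlo error well inside the
asserted bands while keeping the whole suite under a minute of compute.

## Known limitations

No Steiger directionality filtering, proxy-instrument search, MR-RAPS/
contamination-mixture/CAUSE estimators, MVMR-Egger, conditional F
statistics, or joint multi-mediator decompositions — each is outside the
analysis chain this package reproduces. LD must be supplied; the package
never estimates it. The mediated-proportion delta method assumes
independent TE, β₁, β₂; with overlapping samples its CI would be too
narrow.
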