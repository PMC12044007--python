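# Methods

This note records the models each module implements, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical decisions that were genuinely open.

## Meta-analysis (`assoc_meta`)

Study-level allelic odds ratios are combined on the log-odds scale by
classical fixed-effect inverse-variance weighting: β̂ = Σwᵢβᵢ/Σwᵢ with
wᵢ = 1/seᵢ², se = (Σwᵢ)^(−1/2), p = 2Φ(−|β̂/se|). Standard errors are
recovered from printed 95% CIs as (ln hi − ln lo)/(2·1.959964). A
sample-size-weighted z-score scheme is deliberately not implemented: the
standard-error scheme is what reproduces a combined OR from printed
per-study ORs and CIs. Cochran's Q is computed for logging only; no
random-effects model is fitted.

Crude allelic ORs from printed MAFs convert frequencies to allele counts
(2N·f, rounded half-up — MAFs printed to two decimals make the rounding
noise negligible), form the 2×2 table OR with a Woolf standard error, and
apply the Haldane 0.5 correction to zero cells (flagged). A crude OR
computed this way differs from a published covariate-adjusted estimate by
the adjustment, typically a percent or two.

## Fine-mapping (`fine_mapping`)

**Likelihood ratios.** A two-sided p-value maps to a 1-df chi-squared
statistic through the normal quantile, χ² = [Φ⁻¹(1 − p/2)]², evaluated with
scipy's `ndtri`-based inverse survival function. This keeps relative error
below 1e-6 down to p ≈ 1e-300; association tables print p-values at 1e-14
and below, where inverting the complementary CDF naively returns garbage.
The variant-to-tag likelihood ratio is LLR_i = exp((χ²_tag − χ²_i)/2); the
candidate filter keeps LLR ≤ 100 and LD r² > 0.8 (strict on r², tag always
kept) — the conventional "LLR < 1:100" reading under which published
candidate tables (LLR up to ~12) all pass.

**Sum of single effects.** Individual-level dosages are standardized and
the phenotype (0/1 case-control allowed) is treated under a Gaussian
working model, as the reference implementation of this model family does.
Each of L = 10 effects is iteratively refit against the residual of the
others; per-variant posteriors come from Wakefield Bayes factors
BF_j = √(s²_j/(s²_j+σ₀²))·exp(½z²_j σ₀²/(s²_j+σ₀²)). The per-effect prior
variance σ₀² is chosen per iteration from the grid
{0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5, 1}·var(y) (the source analyses do
not state a prior) by maximizing the single-effect marginal likelihood;
σ₀² = 0 is always a candidate, and an effect that selects it carries no
signal and is pruned from PIPs and credible sets — without this pruning
null effects inflate every PIP by ≈ L/m. Residual variance is re-estimated
each sweep from the full-model residuals. Convergence is max|Δα| < 1e-3
(reported, with the iteration count). Credible sets are the smallest
descending-α prefix reaching 0.9 coverage, reported when purity (minimum
pairwise |r| among members) is ≥ 0.5 — the reference default, recorded in
the output since the source analyses are silent on it. Summary-statistic
fitting with external LD panels is out of scope.

## Allele-differential motifs (`allelic_motif`)

PFM counts become log-odds scores with a background-weighted pseudocount
(default 1). Score p-values are exact on a discretized scale: per-position
scores are scaled so the widest position spans ~10,000 integer steps and
rounded; the distribution of the total integer score under the background
is built by convolution, and P(score ≥ s) is a suffix sum. The
discretization error is at most L/(2k) in score units; `score_pvalue` can
return bracketing p-values at thresholds shifted by that bound, and the
test suite checks the DP against exhaustive enumeration (4^L sequences) at
1e-9. SNP scanning evaluates all L windows covering the variant on both
strands (minus-strand hits reported in plus-strand coordinates, 1-based,
closed windows) and takes the hit with the smallest p-value per allele. The
fold change between alleles is max(p₁,p₂)/min(p₁,p₂) with the direction
(stronger allele = smaller p) carried separately.

## Colocalization (`coloc_abf`)

log ABF = ½ln(se²/(se²+W)) + ½z²·W/(se²+W) per variant per trait, with
prior effect sd 0.2 for case-control and 0.15 for quantitative traits (the
defaults of the tool version this stage mirrors; recorded in the result).
The five hypotheses are enumerated with p1 = p2 = 1e-4, p12 = 1e-5 and
normalized in log space; the cross term Σ_{i≠j} is computed as a stable
log-difference, which also makes PP3 exactly zero when only one variant is
shared. Harmonization is an inner join on variant id with the dropped count
available; multi-causal colocalization and conditioning are out of scope.

## Substrate triage (`substrate_triage`)

Following the stated computation literally: a pseudo-count of 1 is added to
all PSM counts, the per-condition medians are taken (midpoint convention at
even replicate counts), fold change = median(bait+1)/median(control+1), and
the p-value is an unpaired two-tailed **equal-variance** t-test on the +1
counts without log transform (the experimental write-ups use unpaired
two-tailed t-tests throughout). The filter requires p < 0.05 and fc > 1.5,
both strict. The pilot list is an input, not recomputed. Dose dependence is
operationalized as a negative least-squares slope of mean abundance on
log10(dose) with a one-sided p < 0.05; an endpoint lowest-vs-highest-dose
two-tailed t-test is also emitted, but the trend test gates the final call.
A final candidate must pass every gate.

## In-silico knockdown (`insilico_knockdown`)

Genes with zero counts in strictly more than 20% of samples are dropped.
TMM factors follow the standard recipe: reference = sample whose
75th-percentile count fraction is closest to the mean; M and A values over
genes positive in both samples are doubly trimmed (30% per tail on M, 5%
per tail on A); the factor is 2^(weighted mean M) with
inverse-asymptotic-variance weights, rescaled to zero log-mean. The
quartile split takes the floor(N/4) lowest and highest samples by
normalized driver expression with stable tie-breaking (N = 328 gives the
canonical n = 82 per extreme quartile; 328/4 is exact, so the tie rule is
moot there).

The exact test re-implements the published qCML scheme rather than wrapping
the package that popularized it — numerical equality with that package is
not claimed; calibration and power are what the tests check. Libraries are
equalized to the geometric-mean library size by a quantile-to-quantile NB
map (mid-p percentile under the source NB, continuously interpolated
quantile under the target NB), alternating twice with common-dispersion
estimation. The common dispersion maximizes the conditional log-likelihood
of the counts given their group sums (equal libraries make the conditional
law free of the mean), optimized over log-dispersion in [1e-4, 10]. The
per-gene two-sided p-value conditions on the total of the rounded
equalized group sums — the group-1 sum follows a negative hypergeometric
law — and sums the probabilities of all splits no more likely than the one
observed (Poisson/binomial limit below dispersion 1e-8). On single NB
observations this reduces to, and numerically matches, the "small-p"
two-sided exact test of the reference package. log2 fold changes use
prior-count-shrunken (0.125) group means. BH FDR is scipy's
`false_discovery_control`, cross-checked against a brute-force step-up
oracle.

Preranked GSEA uses the weighted KS running sum with weight exponent 1 on
|log2fc|, a gene-label permutation null (seed mandatory), NES = ES divided
by the mean |null ES| of the same sign, and the pooled positive/negative
null FDR convention. Sets outside [5, 500] members after intersection are
skipped and logged. The downstream proprietary pathway tool is replaced by
the FDR + fold-change gene-list export only.

## Assay quantification (`assay_quant`)

All quantities go through the standard curve (Ct regressed on log10
quantity; E = 10^(−1/slope) − 1; slope ≥ 0 flags an invalid curve); no
ΔΔCt shortcuts anywhere, matching the kit protocol this stage mirrors.
Percent input scales the input quantity by its dilution factor before the
ratio. Allelic enrichment aggregates replicates as the mean of
per-replicate A/G ratios (not the ratio of means): significance is tested
on the per-replicate ratios, so the estimate and its test should use the
same unit. Luciferase activity is firefly/Renilla per well, folded over
the empty-vector mean; growth series normalize to the first timepoint.

## Synthetic data (`synthetic_data`)

One global integer seed; per-generator streams are derived by fixed,
documented offsets (genotypes +0, phenotype +1000, second trait +2000, PSM
+3000, RNA-seq +4000, qPCR +5000).

* **LD blocks** — haplotypes from a first-order Markov copy process on
  latent uniforms: site j+1 keeps site j's uniform with probability
  `ld_decay`, else redraws. Marginals are exact; with equal site
  frequencies the allelic correlation is exactly `ld_decay`^distance, so
  r² decays geometrically in closed form — ideal for testing r² code. This
  deliberately trades coalescent realism (no recombination hotspots, no
  allele-frequency/LD coupling) for analytic checkability.
* **Case-control summaries** — logistic phenotype on the standardized
  causal dosage, intercept solved to hit the target case fraction;
  per-variant single-covariate logistic **score** tests (closed form, no
  iterative fitting to destabilize small-sample tails). Separated variants
  are flagged, not fatal.
* **Two-trait summaries** — the second (eQTL-like) trait is Gaussian with
  effect 0.5 sd per sd of dosage; the distinct-causal mode picks the
  variant with minimal r² to the first causal and errors (reporting the
  best available r²) if none is below the threshold.
* **PSM tables** — Poisson counts (not NB), matching low-count spectral
  data and keeping the downstream t-test honest about its own normality
  approximation; substrates get a 4× bait effect (the regime the funnel is
  designed for) and expected dose-abundance halving per decade, with 8%
  lognormal replicate noise. Replicate structure (2 bait / 3 control IPs;
  4 doses × 3 replicates) mirrors the experimental design this stage
  emulates. TMT isotope-impurity artifacts are not simulated.
* **RNA-seq** — NB counts, gene means lognormal(5, 1.5), common dispersion
  0.1 (typical for bulk tissue), 328-sample default. A latent per-sample
  factor u ~ N(0,1) scales the driver's mean as 2^u; planted-set genes
  scale as 2^(e·u/2.54), where 2.54 is the expected top-vs-bottom-quartile
  contrast of u, so the realized quartile log2 fold change is ≈ e.
* **qPCR** — Ct = intercept − log10(q)/log10(1+E) + N(0, noise_sd), 5
  ten-fold dilutions from 100 units by default, efficiencies restricted to
  (0.7, 1.1].

Because the generators are stylized, passing tests demonstrate calibration
and recovery **under the stated models**, not robustness to real-data
pathologies (population structure, batch effects, peptide-level artifacts,
expression outliers).

## Problem sizes used in the automated checks

Credible-set coverage is measured over 200 simulated LD blocks (n = 800,
30 variants, r = 0.9 adjacent); NB calibration over 2000 null genes
(NB(50, 0.1), 5 vs 5 samples); substrate recovery over 50 simulated
funnels (200 proteins, 5 substrates); GSEA null calibration over 200
random 20-gene sets at 500 permutations; PWM exactness by full enumeration
at motif length 8. These sizes give binomial/KS resolution comfortably
finer than the thresholds being checked while keeping the whole suite in
the minutes range on one CPU.

## Known limitations

* SuSiE-style fitting requires individual-level data; summary-statistic
  mode with an external LD reference is not implemented.
* The exact test estimates a single common dispersion; tagwise/trended
  dispersion and GLM-based designs are out of scope.
* TMM factors on data with planted differential expression can legitimately
  deviate from 1 when the planted genes shift library composition — the
  factor is then *correcting* composition, and the "close to 1" check holds
  only when the composition shift is small.
* The motif stage scores independent positions against a 0-order
  background; dinucleotide backgrounds and thermodynamic affinity models
  are not implemented.
* Colocalization assumes at most one causal variant per trait in the
  region.
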