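# Methods

tgxpod implements the dose-response inference stack used to derive points
of departure (PODs) from a short-term rodent toxicogenomic study: apical
benchmark-dose (BMD) modeling with a covariate, per-gene transcriptomic
BMD modeling with a filter cascade and aggregation strategies, and a
DEG-count POD statistic (D1/D1*). This note records the models, the
defaults and why, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Apical benchmark-dose model

Continuous endpoints (Ki67 labeling index in percent of hepatocytes,
plasma ALT in U/L) are assumed lognormal. The median response follows one
of two nested model families in the EFSA/PROAST parameterization:

    exponential:  y(x) = a [c − (c − 1) e^(−b x^d)]
    Hill:         y(x) = a [1 + (c − 1) x^d / (b^d + x^d)]

with reduced forms `a·e^(b x)` and `a·e^(b x^d)` nested in the
exponential family. `a` is the background (endpoint units), `b` the
potency (dose⁻¹ or a half-maximal dose for Hill), `c` the fold range,
`d ∈ [1, 8]` the shape. The likelihood is normal on log responses with a
constant log-scale variance per covariate level. Group summaries
(n, mean, SD on the natural scale) are mapped to log-scale sufficient
statistics by the lognormal moment relations `σ²_log = log(1 + CV²)`,
`μ_log = log(mean) − σ²_log/2`, so individual-animal and summary layouts
share one likelihood; a fit from summaries agrees with the fit from the
individuals that produced them to well under 1% at realistic CVs.

The benchmark dose solves `|y(BMD)/y(0) − 1| = BMR` with BMR = 0.10
(a 10% change in the median). BMDL/BMDU are profile-likelihood bounds:
`b` is re-expressed in closed form as a function of the candidate BMD,
the remaining parameters (backgrounds, fold range, shape, variances) are
re-maximized, and the bounds are the extreme BMDs with deviance within
χ²₁(0.90) = 2.706 of the maximum — a two-sided 90% interval, i.e. 95%
one-sided per bound. The bounds were verified against a dense grid scan
of the parameter box on two-parameter problems (≤1% agreement).

**Covariate structure.** Sex and treatment duration combine into one
categorical "study" covariate. By default it sits on the background `a`
and the residual variance; it is additionally placed on the potency `b`
only when that improves AIC by more than 2. With a per-level potency the
BMD differs per covariate level, and the reported POD interval is the
minimum BMDL / maximum BMDU across model families *and* levels; with a
shared potency it is the min/max across the two families only. Sub-models
within a family are chosen by lowest AIC (ties: fewer parameters, then
smaller `b`).

**Exclusion gates.** Series-level exclusions are explicit, never silent:
a series can be dropped when Bartlett's variance-homogeneity test gives
p ≤ 0.05 (the bundled Ki67 covariate table omits the female day-8 series
for this reason, which also lacks a dose response above 750 mkd), and
individual animals flagged by a two-sided single-outlier Grubbs test are
removed before fitting. The bundled male day-29 1500-mkd Ki67 group is
stored outlier-adjusted: the flagged animal's individual value (37.5%) is
known, so the n = 5 summary is recovered exactly from the sum and
sum-of-squares identities.

**Dispersion convention.** The source tables print "mean ± value" without
declaring SD or SE. The default interpretation is SD: the male day-29
1500-mkd entry 10.31 ± 13.35 with a maximum individual value of 37.5% is
arithmetically impossible as an SE of n = 6. The SE interpretation
remains available as a flag.

## Transcriptomic benchmark doses

Each gene's log2 expression is fit by least squares (normal errors,
constant variance) against dose with linear, quadratic, cubic, power
(`β₀ + β₁ x^δ`, δ ∈ [1, 8]), Hill (`β₀ + v x^n/(k^n + x^n)`) and
two-parameter exponential (`α e^(βx)`) models. Goodness of fit is an
F-test against the saturated group-means model. Model choice is
hierarchical: within the nested linear→quadratic→cubic chain the simplest
model not rejected by a likelihood-ratio test at α = 0.05 is retained;
the chain winner competes with power, Hill and exponential on AIC; a Hill
winner with `k` below one third of the lowest positive dose is flagged
and demoted (its half-maximal dose is below the design's support). Ties
break deterministically by parameter count then a fixed model order.
This hierarchy follows the BMDExpress2 convention and is documented as an
interpretation — the tool's exact rule set is not published in full.

The benchmark response is 1.349 residual SD (`σ` from the model fit, not
the control-group sample SD — configurable), the effect size equivalent
to a 10% change at a typical control CV. `bmd_t` solves
`|y(x) − y(0)| = 1.349σ` (closed form for linear/power/Hill/exponential,
smallest positive polynomial root otherwise). BMDL_t/BMDU_t are profile
bounds at the same χ²₁(0.90) threshold (95% per side), holding the
effect-size target at its MLE value while re-optimizing curve parameters
under the constraint that the change at the candidate dose equals the
target. For efficiency the expensive bounds are evaluated only for genes
that already pass the three cheap filter rules; since the cascade is a
pure conjunction the surviving set is unchanged.

**Filter cascade.** A gene's record survives iff fit p > 0.1 AND
BMDU_t/BMDL_t < 40 AND bmd_t ≤ highest tested dose AND maximum observed
|fold change| ≥ 1.5. The fold change comes from the companion DE table
(observed, not model-predicted — configurable), and the prefilter keeps
only genes with strictly positive raw counts in every sample.

## POD aggregation and enrichment

Enrichment of surviving genes in a gene-set collection uses the one-tailed
hypergeometric (Fisher exact over-representation) test with raw p-values —
no multiple-testing correction by default, matching standard rodent
bioassay practice; a BH option exists but is off. A set is reported when
p ≤ 0.1 with ≥ 10 surviving member genes. The universe defaults to the
prefilter-passing genes (not all annotated genes) — a choice the source
analysis leaves open.

Nine aggregation strategies are implemented (median over all surviving
genes; 20 lowest-BMD genes; 20 most induced / most repressed / largest
|FC| genes, ranked by extreme log2FC across doses with FDR then gene id
as tie-breaks; median of enriched-pathway medians; 20 most sensitive
enriched pathways; single most sensitive pathway; pathways common to all
datasets, combined by the arithmetic mean of per-dataset medians). The
registry is extensible; variants beyond the text-attested nine are
one-line additions. Each estimate is classified against the apical
BMDL–BMDU interval as spanning (closed-interval convention), above, or
below.

## D1/D1* DEG-count estimator

The count of genes with |FC| ≥ K and FDR ≤ 0.05 at each positive dose is
fit with the fixed-plateau Hill curve `Count = C/(1 + (d50/dose)^n)`,
C = 1000, by iteratively re-weighted least squares with Poisson
inverse-variance weights `w = 1/max(μ̂, 10⁻⁶)`; weights and fit alternate
until the relative parameter change is below 10⁻⁸ (max 100 iterations).
The control dose is excluded (the model is undefined at zero, where the
DEG count is identically zero). D1 = `d50 (C − 1)^(−1/n)` is the dose at
which the curve predicts a single differentially expressed gene; D1* is
the 5th percentile of D1 over 10,000 parametric bootstrap replicates
(counts redrawn Poisson about the fitted responses, refit with weights
frozen at the inverse of the original fitted responses; a full-IRLS
per-replicate option exists for sensitivity). Non-convergent replicates
are redrawn up to twice the requested number so the percentile sample
size stays fixed; more than 5% permanent failures is a hard error.
Bootstrap refits run as a batched damped Gauss–Newton over all replicates
simultaneously, so 10,000 refits take well under a second.

The plateau is exposed as a parameter: 1000 suits the stricter K ≥ 2
curves, but the 1.5-fold criterion can exceed 1000 DEGs at the top dose,
in which case a plateau above the observed maximum is required for the
curve to be attainable. Monte-Carlo checks at the study design show the
one-sided D1* bound covering the true D1 at close to its nominal 95%
rate (93–95% observed over 200 replicate experiments at 1000 bootstrap
draws).

## Synthetic data generator

The generator emulates the study design — doses {0, 300, 500, 750, 1000,
1500} mg/kg/day, 6 subjects per group — with multiplicative lognormal
noise (unit median, so the generating curve is the quantity the lognormal
likelihood estimates) for apical endpoints, and log2-scale Gaussian noise
for expression. Responsive genes (default 10% of 2000) follow monotone
Hill-shaped log2 curves whose half-maximal dose is solved so that the
analytic benchmark dose — the dose where |Δlog2| = 1.349 × the gene's own
noise SD, exactly the estimand of the transcriptomic BMD stage — equals a
BMD drawn log-uniformly from [100, 1200] mkd; top-dose |log2FC| is
uniform on [0.38, 2.32] (1.3- to 5-fold, matching a weakly acting
compound where half the DEGs fall between 1.5- and 2-fold), direction is
a fair coin, and per-gene noise SD is uniform on [0.15, 0.40] log2 units
(CVs near 25%). Raw counts are an optional Poisson layer around 2^log2.
Genes whose drawn effect cannot reach the benchmark change keep an
undefined true BMD — realistic sub-threshold responders.

The stand-in DE test is a Welch t-test on log2 values with BH correction
within each dose. It is not a count-model DE method and is not claimed to
be: passing tests show the pipeline's internal consistency and parameter
recovery under the generator's assumptions (independent genes, no batch
structure, clean monotone curves, Gaussian log-scale noise), not
performance on real sequencing data with correlated genes, dispersion
heterogeneity or batch effects.

## Problem sizes and numerics

Default analysis sizes: 2000 genes (10% responsive) for the recovery
analysis; 50 simulated studies for apical BMD coverage; 200 outer
replicates × 1000 bootstrap draws for D1* coverage; 10,000 draws for
reported D1* values. Optimizers are bounded quasi-Newton (L-BFGS-B) in
log-parameter space with multi-start over a potency grid; profile bounds
use bracketing plus Brent root-finding with a log-scale bisection
fallback when warm-started profiles are locally rough. Variance estimates
are floored at 10⁻¹² to keep likelihoods finite on noise-free data.
Degenerate inputs (constant responses, all-zero or plateau-saturated
counts, curves that never attain the benchmark response) raise explicit
errors or set flags rather than returning silent numbers.

## Known limitations

- The apical analysis fits printed group summaries; the source analysis
  fit individual animals. The lognormal moment conversion makes the two
  nearly — not exactly — equivalent, which is why reproduction of the
  published BMD bounds is asserted at ±30% rather than printed precision.
- The per-level-potency covariate decision (AIC gate at 2) changes which
  quantity "min BMDL / max BMDU" ranges over; both structures are
  reported in the fit list so the choice is auditable.
- The transcriptomic hierarchy approximates an unpublished rule set;
  agreement with BMDExpress2 is conventional, not bit-for-bit.
- No curated ontologies are bundled; pathway-based strategies run on
  user-supplied GMT files or the synthetic module sets in the analysis
  scripts.
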