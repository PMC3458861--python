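# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `hfcpipe`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Diversity indices

All three indices are computed per individual over its typed loci, from
allele frequencies pooled across sites and years (the intended use case is a
weakly structured population; per-group frequency pooling is available by
subsetting the genotype table). Missing calls are excluded from every sum; a
call with exactly one missing allele is demoted to fully missing rather than
guessed.

- `sMLH = Σ_l h_il / Σ_l H_l`: the denominator sums the population observed
  heterozygosity of exactly the loci the individual was typed at, which
  corrects for panels with missing data; the population mean is ~1 by
  construction.
- `IR = (2H − Σ f_i) / (2N − Σ f_i)`: Σ f_i sums the pooled frequency of all
  2N carried allele copies, a homozygote contributing its allele's frequency
  twice. This convention makes a heterozygote at an even-frequency biallelic
  locus score −1 and weighs homozygosity for rare alleles more heavily —
  the behavior the index is designed for. Pooled frequencies include the
  focal individual by default; a leave-one-out option exists for sensitivity
  analysis (with small samples a private allele can then vanish from the
  pool; its frequency is taken as 0).
- `HL` uses the plug-in expected heterozygosity `E = 1 − Σ p²` per locus,
  not the unbiased `(2n/(2n−1))` version, which keeps HL inside [0, 1] by
  construction. The unbiased estimator is used for *reported* per-locus He
  summaries; the two uses are deliberately distinct.

## Hardy–Weinberg testing

The exact test is Monte-Carlo: the 2n observed allele copies at a locus are
repeatedly shuffled into n random diploids and the heterozygote count
compared with the observed one. The default alternative is one-sided toward
heterozygote deficit (the direction relevant to null alleles and inbreeding);
an excess-sided and a two-sided variant (doubling the smaller tail) are
options. The reported p carries the +1/(N+1) correction and is therefore
valid but conservative on the discrete heterozygote-count support; for
calibration studies a randomized (mid-) p-value — exactly Uniform(0,1) under
the null — is available and is what the uniformity suite checks. Loci with
fewer than 5 typed individuals (configurable, lowered only for validation
against exhaustive enumeration on tiny cases) or a single allele return an
explicit "not testable" status. Bonferroni flags use `p < α / n_tests` over
the testable loci.

## Burden models

Counts use the NB2 negative binomial with log link (`Var = μ + μ²/θ`);
richness uses a Gaussian linear model. The NB fit alternates IRLS for the
coefficients at fixed θ (via statsmodels' GLM with a negative-binomial
family) with bounded one-dimensional profile maximum likelihood for θ
(θ ∈ [1e−3, 1e6], optimized on the log scale), to relative log-likelihood
tolerance 1e−8 within 100 outer iterations. Standard errors are conditional
on θ̂, the usual GLM convention. A fit whose 95% profile interval for θ
reaches the upper bound (log-likelihood within 1.92/2 of the Poisson limit)
is flagged as a boundary fit rather than silently accepted. The Gaussian
log-likelihood uses the ML variance `σ̂² = RSS/n`.

**Parameter count.** `k` = number of regression coefficients including the
intercept, plus one for the dispersion parameter (θ or σ²). This is the
convention under which the parameter counts of the reference ranking tables
checked in the acceptance suite reconstruct exactly from their model labels
(e.g. aggregation + food + month (5 levels, 4 dummies) + 6-level area ⇒ 12
coefficients + θ = 13).

**Standardization.** Continuous effect-size predictors (the diversity metric
and its quadratic) are 2-SD standardized: `(x − mean)/(2·sd)`, sample sd,
giving mean 0 and SD 0.5 so their coefficients are comparable to binary
predictors'. The quadratic column is the square of the already-standardized
base, itself re-standardized — the only reading under which both columns
carry SD 0.5. Categorical and binary predictors are not standardized.

**Design encoding.** Treatment (dummy) coding with a declared reference
level per categorical; interactions are products of the encoded columns of
their parts (main effects are separate terms). A quadratic term requires its
base *data column*, not a linear term in the model: purely curvilinear
candidates are legitimate members of the selection set. Rank-deficient
designs and unseen category levels raise immediately with the offending
columns named.

## Two-stage selection and averaging

Stage one fits an a-priori non-genetic candidate list and shortlists models
with ΔAICc ≤ 2 (boundary inclusive). Stage two expands each shortlisted
model with {nothing, +G, +G², +G+G²} for the genetic metric G and appends a
source-area covariate to every candidate (guarding against
population-structure artifacts), then re-ranks. AICc =
−2logL + 2k + 2k(k+1)/(n−k−1); weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`;
evidence ratio `Δ_i = exp(ΔAICc_i/2)`; ties broken by smaller k then label.

The 90% confidence set is the smallest ranking prefix with cumulative weight
≥ 0.90; weights are renormalized within it before averaging. Averaging is
conditional ("natural"): a parameter is averaged only over the models that
contain it, with those models' weights renormalized — the convention that
reports a single estimate per parameter without shrinkage toward 0; a
zero-substitution (shrinkage) option exists behind a flag. Unconditional
standard errors follow Burnham–Anderson,
`SE_u = Σ w_i √(SE_i² + (β_i − β̄)²)`, with Wald 95% CIs (z = 1.96) and odds
ratios `exp(β)` mapped through the CI. Reference-level parameters are
written as 0 with no interval. In the ranking TSVs the top row's evidence
ratio is printed as 1.00 (w_best/w_best = 1 by definition; tabulations that
print 0 there are treating it as a Δ rather than a ratio).

## Single-locus decomposition

Run only when the top stage-two model contains a genetic term. The
multilocus term(s) are replaced by one binary heterozygosity indicator per
locus, both models refit on individuals with complete genotypes. The F
comparison uses residual sums of squares (Gaussian) or deviances (negative
binomial) — for the NB case both deviances are evaluated at the locus
model's θ, the multilocus model's coefficients refit at that θ, which makes
the deviance difference well-defined. df1 is the difference in regression
df, df2 the locus model's residual df. The two models are not strictly
nested, so F may be negative; the upper-tail p is still the relevant
summary. Effect sizes are partial correlations `r = t/√(t² + df)` with
Fisher-z intervals (±1.96/√(n−3)); the CI method for such intervals is a
convention choice, made explicit here. The sign test is the exact binomial
(p₀ = 0.5), two-sided by doubling the smaller tail capped at 1; zero effects
are excluded with a logged count.

## Synthetic data generator

The generator emulates a two-year, 12-site (6 source areas, 2 sites each)
mark-recapture study of ~380 hosts with site-level food/aggregation
treatments, and a 14-locus microsatellite panel with 6–19 alleles per locus.
Defaults: allele counts (6…19, mean ≈ 11.3); symmetric Dirichlet frequencies
with concentration 0.7, giving mean expected heterozygosity ≈ 0.78–0.80 at
this panel; per-call dropout 0.03; individual inbreeding coefficients
F ~ Beta(0.5, 9.5) (mean 0.05, SD 0.066), which induces the identity
disequilibrium (heterozygosity correlation across loci) that HFC theory
requires — a two-parameter stand-in for pedigree structure. Treatments are
blocked within areas (5 aggregated-food, 3 dispersed-food, 4 control sites),
so treatment dummies are never collinear with area dummies, mirroring the
blocked field design.

Outcomes derive only from the variables in the truth record. Counts are NB2
via the gamma–Poisson mixture on a log-linear predictor built with the same
design encoding the model stage uses, so recovered coefficients are directly
comparable to generating values. Truth effect sizes and dispersions are
realistic for burden analyses of such systems (e.g. aggregation +0.60, a
July abundance peak, IR² −0.52 on replete ticks; θ = 1.5/1.0/0.3 for
replete/non-replete/louse counts); intercepts are set net of the
covariate-mix multiplier so realized sample means land near the target
descriptives (total ticks ≈ 23 per host, prevalence ≈ 0.96, louse prevalence
≈ 0.52). Richness is a Bernoulli sum over 16 taxa with baseline prevalences
spanning 0.14–0.89 and host-level logit shifts (centered so the realized
span stays on target), then *modeled* Gaussian downstream — deliberately
reproducing, and exposing in tests, that approximation.

What the generator does not emulate: genotyping error and allelic dropout
biased by genotype, null alleles, linkage between markers and resistance
loci, spatial autocorrelation beyond the area label, repeat captures, and
parasite transmission dynamics. Passing tests therefore demonstrate the
statistical machinery under the stated sampling model, not robustness to
those real-data pathologies.

## Problem sizes and reproducibility

The recovery experiment defaults to 100 replicates of n = 1000 hosts with
β_IR² = −0.5 and θ = 1.5, a size at which the model-averaged quadratic
estimate is effectively unbiased (|bias| < 0.1) with near-nominal CI
coverage; the null comparison re-runs it with both genetic coefficients 0.
Calibration suites use 500 replicates (HWE uniformity at n = 100 and 2000
permutations; nested-F uniformity at n = 60). Every generator and test is a
pure function of (configuration, seed): identical seeds give bytewise
identical outputs, and the pipeline's provenance record (config hash, seed,
package versions) suffices to reproduce a run.

## Known limitations

- Model-averaged estimates after selection carry the usual post-selection
  caveats; the conditional averaging convention does not shrink weakly
  supported parameters toward 0.
- The NB standard errors condition on θ̂ and ignore θ's sampling
  uncertainty.
- The F comparison between non-nested multilocus and single-locus models is
  a descriptive variance-explained screen, not an exact test.
- g2-type identity-disequilibrium estimators and mean d² are out of scope;
  g2 would be the natural extension of the diversity module.
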