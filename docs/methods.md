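# Methods

## 1. The Mendelian-randomization model

Let M be the serum marker concentration, D the secondary-event outcome, and
G a biallelic variant coded as minor-allele dose (0/1/2). All marker effects
are modelled on the natural-log scale.

**Stage 1 (genotype → marker).** Ordinary least squares of ln M on the
genotype coding, adjusted for age and sex:

    ln M = α + β_g→m · G + γ₁ · age + γ₂ · sex + ε.

Coefficients are reported as percent change in geometric-mean marker,
100·(exp(β) − 1), with Wald 95% CIs (z = 1.96). Codings: additive (dose) or
genotypic (heterozygote and rare-homozygote indicators against the
common-homozygote reference).

**Stage 2 (marker → disease).** Cox proportional-hazards regression of time
to first event on ln M with covariate adjustment; HR = exp(β_m→d) per unit
ln M.

**Expected genotype → disease effect under causality.** If the marker lies
on the causal path and the variant affects the outcome only through the
marker (no pleiotropy),

    β_g→d = β_g→m × β_m→d,    HR_expected = exp(β_g→d).

**Confidence interval by Monte Carlo.** Draw β_g→m* ~ N(β_g→m, se_g→m) and
β_m→d* ~ N(β_m→d, se_m→d) independently (a correlation switch exists for
sensitivity analyses; the two stages are estimated from disjoint model fits,
so independence is the default), form exp(β_g→m*·β_m→d*), and take the
2.5th/97.5th empirical percentiles over 1,000,000 draws. Standard errors
supplied only as printed Wald CIs are recovered as
(ln hi − ln lo)/(2·1.96), after converting percent bounds to log scale where
needed.

**The comparison.** Observed per-variant HRs from Cox models are placed next
to the expected ones; a row is flagged consistent when the expected point
estimate lies inside the observed 95% CI. Under causality observed ≈
expected; under confounding of the marker-event association, observed
genotype HRs collapse to 1 while the expected ones stay elevated.

**Genotype score.** A weighted allele count Σ(β_i/β_ref)·G_i, with the
reference variant the one with the largest |stage-1 coefficient|, so the
score's stage-1 effect equals β_ref and its expected HR is
exp(β_ref·β_m→d).

## 2. Supporting procedures

- **Hardy-Weinberg equilibrium:** Pearson χ² with 1 df comparing observed
  genotype counts with p², 2pq, q² expectations — no continuity correction,
  refusing monomorphic loci and samples under 10 subjects. Loci with
  p < α (default 0.05, strict inequality) are excluded from association
  models; downstream genotype models raise rather than silently fit an
  excluded locus.
- **Linkage disequilibrium:** two-locus haplotype frequencies from unphased
  doses by EM (double heterozygotes split between phases in the ratio of
  current haplotype-product estimates; convergence tolerance 1e-10),
  reported as D′ and r².
- **Group tests:** one-way ANOVA R² across genotype categories and the
  Kruskal-Wallis rank test (mid-ranks for ties; an all-tied sample returns
  H = 0, p = 1).
- **Multi-locus selection:** forward stepwise OLS with backward pruning,
  deliberately permissive thresholds (enter when the nested-F p < 0.4,
  remove when p > 0.6) so candidate models are generous; every model visited
  on the path is then scored by 10-fold cross-validated PRESS with
  seed-fixed fold assignment, and the PRESS-minimal model is returned.
  Rank-deficient candidate designs are skipped, which lets one of a pair of
  perfectly collinear loci enter but never both.
- **Confounder screen:** each variant against each covariate —
  Kruskal-Wallis for continuous covariates, Pearson χ² on the contingency
  table (no continuity correction) for categorical. Degenerate pairs
  (constant covariate, empty table margin) are counted as skipped, never as
  tested; the significant count at p < 0.05 is compared with its binomial
  null expectation and central 95% interval.

## 3. The synthetic-cohort generator

Because the underlying clinical data are not redistributable, the package
ships a generator that emulates a secondary-prevention cohort:

- genotypes: each locus is the sum of two independent Bernoulli(maf) allele
  draws, i.e. exact Hardy-Weinberg proportions, loci mutually independent;
- covariates: age ~ truncated normal 61 ± 8 on [30, 70]; 15% female;
  latent confounder U ~ N(0, 1), never exposed to downstream stages;
- marker: ln M = marker_base + Σ effect·dose + age_effect·(age − 60) +
  sex_effect·female + confounder_effect_marker·U + N(0, marker_sd);
- events: exponential event times with hazard
  baseline_hazard · exp(beta_marker_hazard·ln M +
  confounder_effect_hazard·U), administrative censoring at
  admin_censor_years, independent exponential dropout at dropout_rate;
  observed time is floored at 1e-9 years to keep Cox fits defined.

Each component draws from its own child stream of
`numpy.random.SeedSequence([seed, stream_id])`, so adding subjects or
components never perturbs the others and a config + seed reproduces a cohort
bit for bit.

Named scenarios: **causal** (marker drives hazard, no confounding),
**confounded** (beta_marker_hazard = 0; U raises both marker and hazard at
0.5 each — marginally the marker predicts events, but genotypes do not),
**null** (no genotype-marker and no marker-event effects).

### Default parameters and rationale

| parameter | default | rationale |
|---|---|---|
| per-allele effects | ln 1.813, ln 1.733 | the +81.3% / +73.3% geometric-mean shifts typical of strong cis instruments for this marker class |
| MAFs | 0.23, 0.26 (plus null loci 0.37, 0.15) | common-variant frequencies matching the instruments emulated |
| beta_marker_hazard | ln 1.33 | HR per unit ln(marker) in secondary-CVD marker cohorts |
| marker_base | 0.25 | with the covariate terms, puts the median marker near 2.4 ng/mL |
| marker_sd | 0.75 | yields per-locus marker R² ≈ 0.15, the explanatory power expected of a strong single instrument |
| age_effect, sex_effect | 0.02 /yr, 0.7 | mild age trend; a large sex shift so adjustment visibly matters |
| baseline_hazard | 0.0165 /yr | calibrated by large-n simulation so ≈15% of subjects have an event within the 8-year window |
| admin_censor_years | 8.0 | typical secondary-prevention follow-up horizon |
| dropout_rate | 0.02 /yr | modest loss to follow-up |

### What the generator does not emulate

Linkage disequilibrium between simulated loci (loci are independent; the LD
code is exercised on constructed haplotypes), population stratification,
assay noise or detection limits on the marker, non-proportional or
time-varying hazards, recurrent events, competing risks, genotyping error,
and missing data (the IO layer and models handle missingness, but the
generator emits complete records).

## 4. Numerical choices

- Cox models use lifelines' `CoxPHFitter` with Efron tie handling; the test
  suite validates it against a hand-rolled Breslow partial likelihood on
  tie-free data (where the two agree exactly) and against brute-force
  maximization on a small fixed dataset.
- OLS via statsmodels; all Wald intervals use z = 1.96 rather than
  t-quantiles, matching epidemiological reporting convention.
- Monte-Carlo percentiles use numpy's default linear interpolation;
  determinism is per `(seed, n_draws)` via `numpy.random.default_rng`.
  An analytic oracle (numerical CDF of the product of two independent
  normals) bounds the MC quantile error below 0.005 at 10⁶ draws.
- HWE exclusion uses strict p < α; a locus exactly at the threshold is
  retained. Missing doses are dropped per locus before counting.
- EM for haplotype frequencies iterates to an L∞ tolerance of 1e-10 with a
  10,000-iteration cap.
- Stepwise CV folds come from a seeded permutation of subject order, so
  selection is reproducible under a fixed seed.
- Pipeline sub-seeds derive from `SeedSequence([master_seed, k])` with a
  fixed index k per stage, reduced mod 2³¹ for library compatibility.

Test problem sizes (e.g. n = 1500–2000 cohorts, 100–300 replicate
calibration runs, 10⁶ MC draws) were chosen to keep the full suite within a
few minutes while leaving comfortable statistical margins; they are choices
of this package, not of any external protocol.

## 5. Limitations

- The MR comparison is qualitative (point-inside-CI consistency), not a
  formal test of the difference between observed and expected HRs.
- Single-marker instruments: no multi-instrument meta-analytic MR
  (IVW, Egger) is implemented.
- The exponential event-time model means proportional hazards holds by
  construction in simulations; model misspecification is out of scope.
- The normal approximation behind the MC propagation inherits the usual
  large-sample Wald assumptions of the stage estimates.
- Back-deriving standard errors from printed two-decimal CIs introduces
  rounding error of up to roughly half a unit in the last printed digit.
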