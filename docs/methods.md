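# Methods

This note documents the models, conventions and numerical choices behind
`spirogwas`, and states what the synthetic-data machinery does and does not
emulate.

## The analysis in one paragraph

A population cohort with spirometry is labelled for airflow obstruction two
ways — FEV₁/FVC (in percent) strictly below 70, and strictly below the
lower limit of normal (LLN), the 5th percentile of an LMS reference given
sex, age and height.  Subjects are stratified by smoking (never = 0
pack-years, ever > 5; the 0–5 gap is excluded).  After SNP-level QC, four
logistic GWASes are run (2 definitions × 2 strata), and agreement between
them is quantified as thresholded hit-set overlap (intersection over union,
in percent) and Pearson correlation of per-SNP p-values and odds ratios.
Two resampling studies probe the overlap: duplicating the cohort k-fold
(pure power effect) and re-dealing case labels at random with the three
case counts held fixed (chance overlap).  Top overlapping SNPs are taken to
validation: inverse-variance fixed-effects meta-analysis across validation
cohorts with a Bonferroni + direction replication rule, SNP × ever-smoking
interaction tests, and cis-eQTL scans in expression data.

## LMS reference and classification

The LMS quantile at standard-normal deviate *z* is
`M·(1 + L·S·z)^(1/L)` for L ≠ 0 and `M·exp(S·z)` at L = 0 (|L| < 1e−12 is
treated as 0; the Box-Cox argument is floored at 1e−12).  Coefficients are
stored per sex on an age grid and linearly interpolated; evaluation outside
the grid raises a domain error rather than extrapolating.  A multiplicative
height term `(height/h_ref)^p` on M is available but defaults to p = 0: the
FEV₁/FVC ratio has little residual height dependence once age and sex are
accounted for.

Classification uses strict inequalities exactly as conventionally written
(< 70, < LLN) at full floating precision; no pre-rounding.  Percentages in
reports are rounded to the nearest integer for display only.  Subjects with
missing or non-positive spirometry are flagged invalid and excluded from
all counts.  The LLN percentile defaults to 0.05 but is an argument, since
"the lower fifth percentile" is a convention, not a law.

The bundled `default_reference()` is synthetic but plausible: median ratio
declining linearly from 86 % (male, age 18) at 0.23 %/year, S = 0.075, L
easing from 1.2 to 0.8 over ages 18–95, females 1 point higher.  Its LLN
crosses 70 % in middle age, so fixed-ratio-only cases concentrate in the
old and LLN-only cases in the young — the age-localised discordance
structure the comparison depends on.  It is **not** the published GLI-2012
spline fit; bit-exact GLI replication is out of scope, and real coefficient
tables can be supplied in the documented TSV format.

## Synthetic cohorts

The generator's defaults emulate the discovery-population structure the
analysis assumes: ~51 % never-smokers, ages clipped-normal (mean 46, SD 14)
on 18–89, sex-specific heights, ever-smoker pack-years 5 + Gamma(1.3, 9.2)
(mean ≈ 17, SD ≈ 11), 45 % of ever-smokers currently smoking, MAFs uniform
on a configurable range, genotypes in Hardy–Weinberg proportions, ~1 %
missing calls.

Spirometry is generated through the *same* LMS reference used for
classification.  Subject *i*'s ratio is the reference quantile at
`z_i = sigma·(eps_i − Σ_j g_ij·beta_j/c − py_i·beta_py/c)` with
`eps ~ N(0,1)`, sigma = `spirometry_noise`, g the allele counts of causal
SNPs, py pack-years, and `c = phi(x0)/(Phi(x0)·(1−Phi(x0)))` the local
probit→logit slope at the baseline LLN threshold `x0 = z_0.05/sigma`.  Two
consequences:

* with sigma = 1 and no causal effects the LLN-case prevalence is 5 % by
  construction (never-smokers); the default sigma = 1.15 widens the
  population beyond its healthy reference — as real cohorts are — giving
  ≈ 7.5 % LLN cases, ≈ 9–10 % fixed-ratio cases and a case-union overlap
  around 50–55 % in never-smokers, close to the structure of published
  population tables;
* a planted per-allele log-odds beta is recovered approximately unbiasedly
  by the downstream logistic scan (the classical 1.702 constant under-scales
  at case rates far from 50 %; the local-slope conversion measured 20/20
  coverage of the 95 % Wald CI over 20 replicates at OR 1.5, versus 18/20
  with 1.702).

FVC is drawn from classical linear sex/height/age equations plus noise and
FEV₁ = ratio × FVC, so `fev1 ≤ fvc` always.  A pack-years liability effect
(default 0.02 log-odds per pack-year) makes ever-smokers' obstruction
prevalence realistically exceed never-smokers'.

Causal SNPs affecting **both** definitions act through the shared latent
ratio.  Definition-specific effects cannot live in the ratio (one number
cannot cross one threshold without approaching the other), so they are
applied post-classification by `plant_label_effects`: carriers' case
probability under the targeted definition is raised multiplicatively
(controls flipped to cases with the probability that makes the marginal
rate ≈ p₀·exp(g·beta)), leaving the other definition's labels — and hence
the shared-case correlation — untouched.

All randomness flows from the single config seed through deterministic
per-stage substreams; equal configs give bit-identical cohorts.  LD is not
simulated (independent SNPs), nor are population structure, relatedness or
imputation — so the generator cannot exhibit stratification-driven λ
inflation or LD-clumping effects, and passing calibration tests here says
nothing about those failure modes in real data.

## QC

Call rate, minor allele frequency among non-missing calls, and the exact
conditional Hardy–Weinberg test (probability-ordering two-sided, computed
by the stable heterozygote-count recurrence; chi-square fallback only above
100,000 non-missing genotypes; monomorphic SNPs return p = 1 by
convention).  Filters are applied once on the full genotyped sample — the
analysis uses a single post-QC SNP set for all four scans — and SNP removal
is idempotent.  Whether HWE should be computed in controls only is
unsettled; the default uses all subjects.

## GWAS engine

Per SNP: case status ~ allele count + covariates, fitted by
Newton-scoring IRLS with step-halving, convergence at relative
log-likelihood change < 1e−10 within 50 iterations, covariance from the
inverse observed information at the optimum.  Non-convergence is reported,
never silently dropped; complete separation is detected via fitted
probabilities at their bounds.  Singular designs raise an error naming the
collinear columns.  Inference is the Wald chi-square(1) test (the default
of the standard GWAS tooling this engine mirrors).

Conventions: effect allele = minor allele within the analysed stratum
(sign flipped when the counted allele is major); missing genotypes deleted
listwise per SNP; covariate sets are fixed-ratio → {sex, age, height},
LLN → {} (those variables already enter the LLN), ever-smokers append
{pack-years, current smoking}; all overridable.  λ is the median observed
chi-square(1) statistic over *converged* SNPs divided by 0.4549.
Interaction tests pool both strata and add genotype × ever-smoking to the
union covariate set.

## Overlap, concordance, resampling

Hits are strict (`p < t`; a p-value exactly at the threshold is not a
hit).  The overlap percentage is intersection over union — the only
denominator that reproduces every published table percentage from its
printed counts.  Correlations are computed on raw p-values and raw ORs as
conventionally reported; because raw-scale r is dominated by extreme ORs, a
log-scale variant is exposed and the scale used is recorded.

Cohort expansion duplicates rows verbatim (no resampling noise), which
leaves point estimates identical and shrinks SEs by exactly 1/√k — the
information matrix scales by k at the unchanged optimum.  Random case
allocation re-deals labels uniformly over a stratum's subjects with
(n70, nlln, nboth) preserved exactly, asserted on every call; covariates
are ignored in the re-deal (a covariate-matched permutation would preserve
more structure but the margin constraint is the defining one).  Note that
because the two definitions share nboth cases, the two permuted scans
remain positively correlated: the null overlap exceeds the naive n·t²
independence value, which is precisely why the permutation null — not the
independence approximation — is the right chance benchmark.  A replicate
with an empty hit union contributes 0 % overlap.

## Meta-analysis, replication, eQTL

Fixed effects with weights 1/SE²; pooled p from the Wald statistic of
beta/SE; Q and I² = max(0, 100·(Q − df)/Q).  I² is computed over the
validation cohorts only.  Direction strings encode each cohort's OR with a
closed no-effect band [0.95, 1.05]; a '0' is direction-compatible with
either sign, so replication requires p below alpha/n_candidates and no two
cohorts with opposing signs.  cis-eQTL scans are OLS of probe expression on
allele count plus covariates for probes annotated within 2 Mb either side
of the SNP (1-based coordinates, SNP position to probe start), with a
Bonferroni threshold of 0.05 / probes-tested-in-window; an empty window is
an empty result, not an error.

## Problem sizes and determinism

The bundled demo configuration runs 2,000 subjects × 5,000 SNPs through
every stage in a few minutes on one CPU; the test suite uses cohorts of
300–20,000 subjects chosen per property (large where a closed form is
checked against sampling error, small where only plumbing is exercised).
Pipeline runs are deterministic given the config seed and byte-identical
across reruns; the manifest records the config hash, package versions and
per-stage counts.

## Known limitations

* The bundled reference is synthetic; absolute prevalences depend on it.
* Raw-scale Pearson correlations are heavy-tail sensitive (documented,
  log-scale alternative provided).
* No LD, ancestry structure, relatedness, dosage data or X-chromosome
  handling; sample-level QC (IBS/PCA) is an interface hook only.
* The liability→log-odds conversion is exact only locally; very large
  planted effects (|OR| far from 1) are recovered with mild attenuation.
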