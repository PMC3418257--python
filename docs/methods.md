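# Methods

## Problem setting

Rare heterozygous variants of the RUNX2 glutamine repeat occur in roughly
4 of every 1000 women.  A multi-cohort screen therefore yields only a
handful of carriers, each measured on a cohort-specific panel of bone
parameters (calcaneal ultrasound: broadband attenuation, speed of sound,
stiffness index; DEXA: femoral neck, lumbar spine, trochanter,
intertrochanteric region, total hip, total body, Ward's triangle, radius
sites).  Sites are strongly correlated within a subject and devices
differ across cohorts, so the analysis works entirely in within-cohort
covariate-adjusted Z-scores, and the carrier group's evidence is
evaluated against a correlated multivariate null by Monte Carlo.

## Adjustment model

Within each (cohort, site), ordinary least squares of the measure on one
of three covariate sets — `age`, `age + weight`, `age + weight⁻¹`
(default `age-winv`) — with the stiffness index log_e transformed first
(its variance scales with its level).  A subject's Z-score is the
residual divided by the n−1 sample SD of residuals, so within each
(cohort, site) the fitted set has mean 0 and sample SD 1 exactly, and the
score is invariant to affine device-unit changes.  Carriers stay in the
fitting set: at ~0.4 % prevalence their leverage is negligible, and the
comparison intended is carrier versus whole-cohort distribution.
Regressions are strictly cohort-specific, even when cohorts share a
device model, because each cohort samples a different age window.

Monozygotic twin pairs are genetically one individual: their per-site
Z-scores are averaged into a single pseudo-subject after scoring (an
error is raised if a pair's carrier flags disagree).  Dizygotic twins
remain separate individuals.

## Empirical multivariate p-value

The carrier group across study blocks b = 1..B contributes n_b carriers
measured on k_b sites with inter-site correlation R_b (pairwise-complete
Pearson over all cohort subjects, forced to unit diagonal and passed
through positive-definite repair: eigenvalues clipped at 1e-8, matrix
rebuilt and rescaled to unit diagonal).  The test statistic is the
unweighted grand mean of all Σ n_b·k_b carrier Z values.  Each Monte
Carlo trial draws n_b independent MVN(0, R_b) vectors per block via
Cholesky factors from per-block PCG64 substreams (derived from one seed
through `SeedSequence`, making the tail count bit-reproducible and
independent of the vectorisation chunk size), and the empirical p is the
plain ratio c/T of trials whose grand mean is **less than or equal to**
the observed mean — a one-sided, tie-inclusive lower tail.  The
(c+1)/(T+1) estimator is available as an option but is not the default,
matching the plain-ratio convention of the reported analysis.  A tail
count of zero is returned as p = 0 with a warning to increase T.

Since the trial statistic is a linear form in jointly normal variables,
its exact null is N(0, V) with V = Σ_b n_b·(1ᵀR_b 1) / (Σ_b n_b·k_b)²,
and Φ(m̄/√V) is attached to every result as `p_closed_form`.  This
closed form is the package's internal oracle: the acceptance suite checks
|p̂ − Φ(m̄/√V)| ≤ 3·√(p(1−p)/T) at T = 200,000 over a grid of group
sizes (1–9), panel widths (1–7) and equicorrelation levels (0–1).  Note
the perfectly correlated case is handled through PD repair, which
perturbs the matrix at the 1e-8 eigenvalue floor; closed-form agreement
there is to ~1e-7 relative, not machine precision.

The grand-mean convention for multi-study composition (rather than
per-study weighting) is a deliberate choice: it treats all carrier
measures as one pooled evidence vector, consistent with quoting a single
overall mean across all variables.  Per-study weighting schemes are not
implemented.

## Rarity and fracture statistics

* **Carrier frequency**: per-subject (carriers / genotyped), not per
  chromosome.  The default computation includes only the four
  volunteer-recruited cohorts (Western Australian, GOS random, TASOAC,
  Aberdeen; 3276 subjects), excluding fracture-recruited and clinic
  series, so ascertainment does not inflate the estimate.  CI by exact
  Clopper–Pearson beta quantiles.
* **Detection interval**: equal-tailed Binomial(n, p) quantile interval —
  lo the smallest integer with CDF ≥ α/2, hi the smallest with
  CDF ≥ 1−α/2; defaults n = 3000, p = 0.004 give (6, 19).
* **Fisher exact test**: two-sided by the point-probability
  (minimum-likelihood) rule — all tables in the fixed-margin orbit whose
  hypergeometric probability is ≤ the observed one (relative tie
  tolerance 1e-7) — the convention of mainstream statistical software.
  Verified against exhaustive integer-arithmetic enumeration for every
  table with total ≤ 60.
* **Odds ratio**: ad/(bc) with a Wald CI on the log scale; any zero cell
  triggers the Haldane–Anscombe +0.5 correction, flagged in the result.

## Synthetic cohort generator

The generator emulates the six-cohort design: cohort names, genotyped
sizes (1078, 822, 598, 980, 385, 991), age ranges, per-cohort site
panels, twin structure only in the Sydney registry cohort, and
incident-fracture follow-up only in the elderly Western Australian
cohort (baseline five-year rate 0.178).

Defaults the source data did not specify, chosen once for realism and
exposed in `StudySpec`:

* weight ~ N(66, 10²) kg, height ~ N(161, 7²) cm (the spread of observed
  carriers), ages uniform on each cohort's range;
* site means/SDs in device units (e.g. femoral neck 0.85 ± 0.13 g/cm²)
  with slopes ≈ −0.3 SD per decade of age and a weight⁻¹ term spanning
  ≈ 0.27 SD over the weight range — only the adjusted-Z structure
  matters downstream;
* inter-site correlation 0.75 within ultrasound, 0.70 within DEXA, 0.40
  between modalities;
* MZ co-twins share genotype exactly (copied, never redrawn) and share a
  latent trait component (correlation 0.75; halved for DZ), plus birth
  date;
* allele labels sampled with weights proportional to observed counts
  (16Q 12/20, 30Q 5/20, 18Q 2/20, 15Q 1/20); all carriers heterozygous.

The carrier flag is Bernoulli with the per-subject carrier frequency
(default 0.004); the implied allele frequency q satisfies 2q − q² =
carrier frequency exactly, so the heterozygote-probability invariant and
the observed prevalence coincide by construction.  The carrier effect
(default −0.7 SD) shifts every site's latent standard value additively.
Incident fracture is Bernoulli with logit(p) = logit(baseline) − ln(2)·Z*_FN,
i.e. odds doubling per SD of femoral-neck deficit.

What the generator does **not** model — and hence what passing tests do
not show about real data: genotyping error, non-normal phenotype tails,
secular/batch drift within a cohort, informative missingness, age-varying
covariate effects, and fracture risk pathways other than femoral-neck
density.

The amplicon simulator builds sequences `forward primer + 100 nt flank +
(CAG/CAA)^nQ (GCN)^nA + 76 nt flank + revcomp(reverse primer)`, fixing
total length at 216 + 3·(nQ + nA) bp so the 23Q/17A wild type is the
assay's 336 bp fragment.  Flank content is seeded-random but screened so
the designed repeat is the unique in-frame glutamine run and the primer
sites are unique; boundary codons are fixed (ATG before, GAT after) so
the designed runs are maximal.  Absolute flank composition is
conventional — only length differences between alleles (3 bp per codon,
±21 bp for the common variants) are asserted.

## Numerical choices and degenerate inputs

* OLS via statsmodels; singular designs (constant covariate) and
  numerically perfect fits (residual SD ≤ 1e-12 relative) are errors —
  a zero-variance measure cannot be standardized.
* Zero-variance sites abort correlation estimation with the site named;
  pairwise-complete estimation requires ≥ 10 complete pairs.
* One-sample carrier tests use the t distribution (two-sided); with one
  observation the mean is reported and p omitted; a zero-variance sample
  already at the null mean gets p = 1.
* Detection and CP intervals use scipy's beta/binomial quantiles; the
  closed-form tail uses the scipy normal CDF (tests cross-check against
  `erfc`).

## Problem sizes used in the test suite

Statistical guarantees are verified at sizes chosen for tight Monte
Carlo error at reasonable cost: the oracle grid at T = 200,000 trials
per design; null calibration over 1000 synthetic replicates of a
600-subject, four-site cohort with carrier frequency 0.03 (so each
replicate contains a testable carrier group) and T = 2000 per empirical
p; effect recovery over 500 replicates of the full four-cohort volunteer
suite at the study's own carrier frequency; correlation recovery at
n = 20,000 subjects.

## Known limitations

* The reported empirical p-values of the original screen (0.0025,
  0.0024, 0.0007, 0.0009) are not recomputable: the observed per-cohort
  correlation matrices and per-carrier multi-site Z vectors were never
  published.  The package reproduces the construction, and its demo
  (equicorrelated R ≈ 0.55) lands in the same order of magnitude.
* The published fracture statistics (Fisher p = 0.036, OR 4.7) rest on an
  unprinted integer fracture count and a covariate-adjusted logistic
  model; the package's contingency reconstruction (4, 4, 184, 852) gives
  p ≈ 0.039 and OR ≈ 4.63, reported as demo outputs only.
* Logistic regression with covariates, ANCOVA covariate testing, device
  cross-calibration and any multiple-testing correction across sites are
  out of scope.
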