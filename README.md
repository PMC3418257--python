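# qrepbmd

Statistical toolkit for asking a deceptively simple question: when a
handful of carriers of a rare variant — here, glutamine-repeat (Q-repeat)
variants of the bone transcription factor RUNX2, found at a carrier
frequency of roughly 0.4 % in adult women — are scattered across several
epidemiological cohorts measured on different densitometers, do they sit
significantly below the population mean in bone density?

The package is aimed at genetic epidemiologists working with very small
carrier groups (n ≈ 5–25) and multiple correlated phenotypes, where
standard per-site tests waste most of the information and naive pooling
of raw measures across devices is meaningless.

## The analysis

1. **Within-cohort adjustment.** For each cohort and skeletal site, the
   raw measure `y` (DEXA BMD in g/cm², calcaneal ultrasound BUA/SOS, or
   log-stiffness) is regressed by OLS on covariates (default: age and
   weight⁻¹) and each subject is expressed as a Z-score,
   `z = (y − ŷ) / s_resid`, dimensionless SD units around the cohort
   regression mean.  Z-scores are invariant to affine device-unit changes,
   so carriers can be pooled across cohorts and machines.  Monozygotic
   twin pairs are averaged into single genetically unique pseudo-subjects.

2. **Empirical multivariate p-value.**  The carrier group's evidence is
   the grand mean m̄ of all its Z-scores across sites and studies.  Under
   H₀, carriers are ordinary draws from MVN(0, R_b) per study block *b*,
   with R_b the inter-site correlation observed in that cohort.  Monte
   Carlo trials redraw same-sized groups and count the fraction with a
   grand mean ≤ m̄ (tie-inclusive, one-sided):

       p̂ = #{trials: mean ≤ m̄} / T

   Because the statistic is linear in jointly normal variables, the exact
   null is N(0, V) with

       V = Σ_b n_b·(1ᵀR_b1) / (Σ_b n_b·k_b)²,

   and `closed_form_p` returns Φ(m̄/√V) alongside every empirical result
   as a built-in oracle.

3. **Rarity and fracture.**  Carrier frequency k/n with an exact
   Clopper–Pearson CI; an equal-tailed binomial quantile interval
   predicting the carrier yield of a future study; Fisher's exact test
   (point-probability rule, full hypergeometric enumeration) and a Wald
   odds ratio for carrier-by-fracture 2×2 tables.

4. **Synthetic cohorts.**  A generator reproduces the six-cohort study
   design (volunteer cohorts totalling 3276 genotyped women, carrier
   frequency 0.004, additive latent deficit −0.7 SD, MZ twin sharing,
   fracture odds doubling per SD of femoral-neck deficit), so every stage
   is testable with known ground truth.  A companion utility simulates
   the 336 bp exon-1 amplicon and calls poly-Q/poly-A repeat lengths
   (wild type 23Q/17A; the common 16Q/30Q variants shift the fragment by
   ∓21 bp).

## Worked example

Six carriers measured on seven correlated bone parameters, observed
grand mean −0.74 SD, equicorrelation 0.55:

```python
from qrepbmd.monte_carlo import Block, CorrelationModel, GroupDesign, empirical_p

sites = ["BUA", "SOS", "STIFF", "FN", "TR", "INT", "HIP"]
design = GroupDesign([Block("WA", 6, CorrelationModel.equicorrelated(sites, 0.55))])
r = empirical_p(design, observed_mean=-0.74, trials=100_000, seed=7)
print(r.tail_count, r.p_empirical, round(r.p_closed_form, 6))
```

```
1051 0.01051 0.010369
```

1051 of 100,000 simulated six-carrier groups were at least as deficient
as the observed one: an empirical multivariate p of 0.011, in close
agreement with the analytic tail 0.0104.  Had the seven sites been
treated as independent the same mean would look absurdly extreme
(Φ(−0.74·√42) ≈ 8×10⁻⁷) — modelling the correlation is the whole point.

The frequency stage, from the observed volunteer-cohort counts:

```python
from qrepbmd.rarity_and_fracture import carrier_frequency, detection_interval

est = carrier_frequency(13, 3276)
print(round(est.estimate, 3), round(est.ci_low, 3), round(est.ci_high, 3))
print(detection_interval(3000, 0.004, 0.95))
```

```
0.004 0.002 0.007
(6, 19)
```

i.e. a carrier frequency of 0.004 (95 % CI 0.002–0.007), with 95 % of
future ~3000-subject studies expected to detect between 6 and 19
carriers.

The full pipeline (simulate → adjust → summarize → Monte Carlo →
frequency → fracture) runs from one config and one seed:

```bash
qrepbmd run-all --seed 1 --out runs/demo
```

and writes per-stage CSV/JSON artifacts plus a manifest of output hashes;
identical config and seed reproduce the manifest byte for byte.

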