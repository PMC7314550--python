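# Methods

`ptvburden` implements a complete, self-contained version of a rare-variant
burden survival analysis: how the germline count of ultra-rare
protein-truncating variants (PTVs) relates to lifespan (survival during a
biobank follow-up window) and healthspan (age at first chronic disease), and
what that implies in years of life. Because the real cohort data (exome-level
genotypes joined to mortality registries) cannot be redistributed, the
package ships a first-class synthetic-cohort generator whose defaults encode
the study conditions, and every downstream stage is validated against it.

## Models

### Burden definition

A PTV is a stop gain, frameshift, or canonical splice donor/acceptor
disruption annotated on a gene's canonical transcript. Variants are assigned
to four minor-allele-frequency bins, half-open so they partition [0, 0.2):

| bin | interval |
|-----|----------|
| 1 (ultra-rare) | [0, 1e-4) |
| 2 | [1e-4, 1e-3) |
| 3 | [1e-3, 1e-2) |
| 4 | [1e-2, 0.2) |

The exposure of interest is the bin-1 PTV count per genome. Burden counts
variant *sites* carried (heterozygous or homozygous = 1); an allele-dosage
mode is provided but not the default, because ultra-rare sites are almost
always heterozygous and the site count is what the 0–3 / 4–5 / 6–7 / 8–9 /
10+ group stratification assumes.

Site filters before any counting: autosomes only, polymorphic, genotype
missing rate < 10%, MAF < 0.2. Filters are per-site, hence order-independent
and idempotent.

### Mortality risk (Cox, follow-up scale)

Survival during an 11-year follow-up is modelled with a standard Cox
proportional-hazards model, covariates including burden, sex and the age at
first assessment. With a Gompertz population hazard
`h = h0 exp(Gamma * age)`, the hazard during follow-up factorises as
`h0 e^{Gamma t} * exp(Gamma * a + beta * n + beta_sex * s)` for assessment
age `a`, so the Cox coefficient on assessment age consistently estimates the
Gompertz slope Gamma, and the model requires no life-history (left-
truncation) information.

The partial likelihood uses Efron's tie correction and is maximised by
Newton–Raphson with step-halving; convergence is declared at gradient
infinity-norm < 1e-8 (the ascent check uses a tolerance scaled to the
log-likelihood magnitude so floating noise cannot stall it). Standard errors
come from the observed information; Wald two-sided p-values and intervals.
Rank-deficient designs raise instead of returning arbitrary coefficients.
A monotone partial likelihood (perfect separation) drives the gradient to
zero at runaway coefficients, so the fitter additionally warns whenever a
standardised coefficient exceeds 10 (hazard ratio e^10 per SD).

### Morbidity risk (Gompertz-PH maximum likelihood, age scale)

Healthspan events frequently precede enrolment (roughly a quarter of
participants already carry a qualifying diagnosis at assessment), so the
follow-up Cox construction is unusable. Instead the age at first disease (or
the censoring age, end of follow-up) enters a fully parametric
proportional-hazards model with Gompertz baseline,

    h(t) = h0 * exp(Gamma * t + x @ beta)
    l = sum_i [ d_i (ln h0 + Gamma t_i + x_i beta)
                - (h0 / Gamma) e^{x_i beta} (e^{Gamma t_i} - 1) ]

with no delayed entry, on the assumption that disease incidence does not
materially affect enrolment. Optimisation is over `(ln h0, ln Gamma, beta)`
so positivity is structural: a bounded quasi-Newton pass (L-BFGS-B) provides
a robust start, then Newton steps with a finite-difference Hessian of the
analytic score polish to gradient norm < 1e-8. `ln Gamma` is floored at
`ln 1e-8`; data generated at Gamma = 0 are fitted at that exponential edge
and recover the closed-form constant-hazard MLE `h0 = events / total time`.
`h0` and `Gamma` are estimated jointly (not profiled); their Wald intervals
are formed on the log scale and exponentiated, keeping them positive.

### Translating log-hazards into years

Under the Gompertz-PH model a covariate coefficient beta is exchangeable
with `beta / Gamma` years of age: `years_per_unit(beta, Gamma) = beta/Gamma`,
the mortality-rate doubling time is `ln 2 / Gamma`, and a burden standard
deviation `sd` maps to `sd * beta / Gamma` years of lifespan variability.
Two Gamma values circulate in the source analyses (0.087 from the survival
fit, 0.093 used in the conversion narrative); both are accepted inputs and
the package takes no side — the worked examples state which value they use.
(Note the published 0.16 yr/mutation for healthspan equals 0.014/0.087;
0.014/0.093 gives 0.151.)

### Somatic accumulation bound

Somatic cells acquire mutations at roughly `R = 1e-8` per bp per year. With
genome size `L = 3e9` bp and a fraction `lambda = 0.33e-5` of the genome at
which a hit would create an ultra-rare PTV (a 10-kbp footprint), the somatic
ultra-rare PTV burden grows as `lambda * L * R * t` and contributes a linear
log-hazard term with slope `beta * lambda * L * R ≈ 4.6e-6` per year —
negligible against the Gompertz slope of ~0.09/yr (ratio ~5e-5; the verdict
threshold defaults to 1e-2). The arithmetic is deliberately exposed as tiny
pure functions so the scaling properties are testable.

### Gene-level statistics

* **Constraint scan**: per gene, a 2x2 Fisher exact test of ultra-rare
  stop-gain + frameshift counts versus synonymous counts (all frequencies, a
  coverage-normalising neutral read-out), against the totals in the rest of
  the gene set; Bonferroni correction; genes with adjusted p < 0.05 are
  labelled *prone* (OR > 1) or *intolerant* (OR < 1). Splice-site variants
  are excluded from the PTV tally because their per-gene count scales with
  intron number.
* **Split-cohort burden scan**: individuals ordered by lifespan or
  healthspan are split into two equal halves (stable sort by (value, id);
  odd cohorts give the lower half the extra member — a deterministic
  convention); per gene, *unique* carrier individuals per half versus total
  carriers per half, two-sided Fisher, Benjamini–Hochberg FDR at 0.05.
  Uniqueness is per individual (an individual with two qualifying variants
  in a gene counts once).
* **iPTV genes**: the set difference between the gene universe and genes
  harbouring at least one ultra-rare PTV.
* **NMD 50-bp rule**: a premature stop triggers nonsense-mediated decay iff
  it lies strictly more than 50 nt upstream of the last exon–exon junction
  in spliced-transcript coordinates; exactly 50 nt escapes (the convention
  of the annotation tools this mirrors; the distance is configurable).
  Single-exon transcripts never trigger. The rule operates purely in spliced
  coordinates and is therefore strand-invariant.
* **Expression breadth**: fraction of tissues with TPM > 10.
* **Group comparisons** of annotation metrics (oe, GHIS, indispensability,
  dN/dS, breadth): Wilcoxon rank-sum, Student t, or Fisher on a binarised
  metric, all two-sided.

## Synthetic cohorts

The generator's defaults are the study conditions:

| parameter | default | meaning |
|-----------|---------|---------|
| burden_mean | 6 | ultra-rare PTVs per genome |
| burden_dispersion | 2.6^2/6 ≈ 1.127 | variance/mean; gives SD 2.6 |
| gompertz_slope | 0.09 /yr | log-hazard slope for mortality and morbidity |
| beta_burden | 0.046 /mutation | lifespan log-hazard per ultra-rare PTV |
| beta_burden_healthspan | 0.014 /mutation | healthspan counterpart |
| beta_sex | 0.47 | male excess mortality log-hazard |
| beta_sex_healthspan | 0.16 | male excess morbidity log-hazard |
| assessment_age_range | 40–70 yr | uniform enrolment ages |
| followup_years | 11 | censoring horizon |
| baseline_hazard | 4.5e-6 /yr | mortality h0 at age 0 |
| morbidity_baseline_hazard | 1.1e-4 /yr | morbidity h0 at age 0 |

Burdens are negative binomial (mean, variance/mean); a Poisson at ratio 1.
The Poisson alternative at mean 6 has SD 2.45, slightly below the observed
2.6, which is why the dispersion knob exists. Event ages are drawn by exact
inversion of the Gompertz-PH survivor function; at Gamma = 0 the exponential
limit is used. Individuals whose simulated death precedes their assessment
age are re-drawn conditional on surviving to assessment — implemented as
closed-form conditional inversion, which is distributionally identical to
rejection-resampling with the individual's covariates held fixed. Disease
ages are generated independently of assessment, so healthspan events may
precede enrolment, as in the emulated design.

The two baseline hazards are not reported by any source and were calibrated
once from the model's own survival integral: 4.5e-6/yr makes the expected
share of deaths within follow-up ≈ 2.8% (averaging the burden and sex hazard
multipliers over the cohort composition, matching the emulated cohort's
1,122 deaths among 40,368), and 1.1e-4/yr puts the median disease-free age
near 70. These values are below period life-table baselines on purpose: the
emulated cohort is healthier than the general population.

The variant table is generated so that ultra-rare PTV carriages aggregate
*exactly* to the burden table's bin-1 column: each individual's count is
scattered over distinct singleton-scale sites (about 1.2 carriers per site).
For those constructed sites the stored MAF is carriers/(2N) when that is
below 1e-4, otherwise a reference-panel-style draw below 1e-4 — small
cohorts cannot resolve ultra-rare internal frequencies, and the binning must
remain consistent with the generating burden. Background sites (synonymous
everywhere; PTVs in bins 2–4) draw MAF log-uniformly within bin and sample
carriers binomially (expected allele count 2N x MAF), with homozygotes
arising from repeated draws. A configurable 11% of genes is held out of
ultra-rare PTV assignment, giving a ground-truth iPTV set. Per-gene
single-transcript models (1–8 exons, 80–300 bp each) provide spliced
coordinates for stop-gain placement and NMD prediction. Parental ages at
death come from a binomially thinned share (default 0.5) of the child's
burden plus an independent top-up, dying under the same Gompertz law with a
population-scale baseline (4e-5/yr) and censoring at the child's assessment
age plus a 28-year generation gap — an explicit stand-in: no generative
model for parental phenotypes is specified anywhere, and the component
exists so the parental-survival code paths are exercisable.

What the generator does **not** emulate: linkage disequilibrium and
recombination, population structure (the principal-component covariates are
pure noise), genotype missingness patterns, multi-transcript genes,
relatedness, secular cohort effects, and any correlation between burden and
assessment age. Passing tests therefore demonstrate that the estimators
recover the parameters of this idealised generative process — internal
consistency and statistical correctness — not that the effect sizes would
replicate in any real cohort.

## Numerical and design choices

* Efron tie handling (accurate default; the sources are silent on ties).
* Wald two-sided p-values and CIs throughout, matching the CI style of the
  emulated reports.
* MAF bin boundaries half-open upward (a boundary value belongs to the
  upper bin): the verbal definitions use strict inequalities on both sides,
  which would leave boundary points unassigned.
* MAF source pluggable: internal cohort MAF by default, or an external
  reference column with variants absent from the reference dropped (the
  small-cohort mode, where absence from a large panel flags a likely
  artefact).
* Degenerate inputs raise rather than return: all-censored data, zero
  events, empty groups/universes, rank-deficient designs, all-missing
  genotype vectors.
* Exact-test calibration checks (uniform null p-values) are run at large
  per-gene counts (hundreds of carriers or variants per gene): Fisher's
  exact test is conservative and discrete, and at realistically small
  counts its null p-value distribution is visibly super-uniform; the large-
  count regime isolates the implementation property being tested. The
  FDR-discovery count is checked at both scales.
* Monte-Carlo problem sizes used by the test-suite and acceptance script:
  50 replicates of n=20,000 for Gompertz recovery, one n=40,000 cohort for
  the Cox fit, n=100,000 event ages for the hazard-slope regression, 1,000
  genes for the null scans. These sizes keep every standard error a small
  fraction of the tolerances they are tested against.

## Known limitations

* The Gompertz-PH fitter assumes no delayed entry; fitting left-truncated
  data will bias `h0` (the slope is remarkably robust in practice, as the
  recovery tests show, because the likelihood is dominated by the event-age
  spread).
* The Cox implementation targets modest covariate counts (tens); it builds
  an n x p x p tensor per Newton step and is not tuned for p in the
  hundreds.
* The split-cohort burden test ignores censoring: "lifespan" means the
  observed ordering variable, exactly as in the emulated design.
* The NMD rule is the classical 50-bp heuristic; it ignores the additional
  escape clauses (long exons, start-proximal stops) of newer annotators.
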