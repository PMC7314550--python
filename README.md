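# ptvburden

Rare-variant burden survival analysis: how the germline count of ultra-rare
protein-truncating variants (PTVs) relates to human lifespan and healthspan,
and what a log-hazard coefficient means in years of life.

Every genome carries a handful of ultra-rare (minor allele frequency
< 1e-4) variants that truncate proteins — stop gains, frameshifts, and
canonical splice-site disruptions. This package is for statistical
geneticists and biodemographers who want to run, validate, or extend the
burden-versus-survival analysis end to end without access to protected
biobank data: it bundles a synthetic-cohort generator that reproduces the
statistical structure of an exome-sequenced biobank (burden distribution
with mean 6 and SD 2.6 per genome, Gompertz mortality and morbidity with
log-hazard slope Γ ≈ 0.09/yr, an 11-year follow-up design), the variant
filtering/classification layer, and the estimators themselves.

## The models

Two proportional-hazards models carry the analysis:

* **Mortality risk** — a standard Cox model on the follow-up time scale,
  `h(t) = h₀(t) exp(β·n + β_sex·s + Γ·a + …)`, with burden `n`, sex `s` and
  age at assessment `a` as covariates (Efron ties, Newton–Raphson, Wald
  inference). Because the population hazard is Gompertz, the coefficient on
  assessment age estimates the Gompertz slope Γ.
* **Morbidity risk** — a parametric Gompertz-baseline PH model on the age
  scale for disease-free survival, maximising

      ℓ = Σᵢ [ dᵢ(ln h₀ + Γtᵢ + xᵢβ) − (h₀/Γ) e^{xᵢβ}(e^{Γtᵢ} − 1) ]

  over `(ln h₀, ln Γ, β)`.

Coefficients translate into years by equating log-hazard contributions:
each burden unit costs `β/Γ` years, the mortality-rate doubling time is
`ln 2 / Γ`, and a burden SD maps to `SD·β/Γ` years of lifespan variability.
A companion module bounds the somatic contribution: somatic PTVs accumulate
as `λLR·t` (genome fraction λ, genome size L, mutation rate R), adding a
linear log-hazard slope `βλLR ≈ 4.6e-6`/yr — negligible against Γ ≈ 0.09/yr,
so somatic PTV accumulation cannot explain Gompertz mortality acceleration.

Gene-level statistics round out the pipeline: a PTV-versus-synonymous
constraint scan (Fisher + Bonferroni; *prone*/*intolerant* labels), a
split-cohort gene burden test (Fisher + Benjamini–Hochberg), identification
of genes free of ultra-rare PTVs (iPTV), the 50-bp nonsense-mediated-decay
rule on transcript models, tissue expression breadth (TPM > 10), and group
comparisons of constraint metrics (oe, pLI, GHIS, dN/dS).

## Worked example

```python
import pandas as pd
from ptvburden import (SimulationConfig, simulate_cohort, compute_burden,
                       fit_cox, fit_gompertz_ph, years_per_unit, doubling_time)

cfg = SimulationConfig(n_individuals=40_000, seed=7)
cohort = simulate_cohort(cfg)          # phenotypes, burden table, variants
pheno = cohort.phenotypes

matrix = compute_burden(cohort.variants, list(pheno["id"]))
pheno = pheno.assign(burden=matrix.ultra_rare_ptv().to_numpy())

cox = fit_cox(pheno, "time", "event", ["burden", "sex", "age_assessment"])
print(cox.summary().round(4))

gomp = fit_gompertz_ph(pheno, "healthspan_age", "healthspan_event",
                       ["burden", "sex"])
print(gomp.summary().round(4))

beta, gamma = cox.params["burden"], gomp.gamma
print(f"gamma = {gamma:.4f}, doubling time = {doubling_time(gamma):.2f} yr")
print(f"burden effect = {years_per_unit(beta, gamma):.3f} yr of lifespan "
      "per ultra-rare PTV")
```

Output:

```
                  coef      se  ci_lower  ci_upper       p      N  events
burden          0.0305  0.0117    0.0076    0.0534  0.0089  40000    1050
sex             0.5175  0.0654    0.3894    0.6457  0.0000  40000    1050
age_assessment  0.0956  0.0043    0.0872    0.1039  0.0000  40000    1050

          coef  ci_lower  ci_upper    p      N  events
h0      0.0001    0.0001    0.0001  NaN  40000   18168
gamma   0.0896    0.0885    0.0907  NaN  40000   18168
burden  0.0182    0.0127    0.0238  0.0  40000   18168
sex     0.1679    0.1386    0.1973  0.0  40000   18168

gamma = 0.0896, doubling time = 7.73 yr
burden effect = 0.341 yr of lifespan per ultra-rare PTV
```

Reading it: the cohort was generated with burden log-hazards 0.046
(lifespan) and 0.014 (healthspan), male excess 0.47/0.16, and Γ = 0.09. The
Cox fit recovers a positive burden effect whose CI covers 0.046 and reads
the Gompertz slope off the assessment-age coefficient (0.0956); the
morbidity model recovers Γ = 0.0896 and the healthspan burden effect
(0.0182, CI covering 0.014); the translation layer then prices one
ultra-rare PTV at about a third of a year of lifespan for this replicate
(the generating value is 0.046/0.09 ≈ 0.5 yr, within the fit's CI).

A thin CLI mirrors the library: `ptv-burden simulate`, `ptv-burden burden`,
`ptv-burden fit`, `ptv-burden translate`, `ptv-burden gene-tests`
(`--help` on each). The variant TSV dialect has columns
`chrom pos ref alt gene transcript canonical effect maf missing_rate
carriers hom_carriers stop_position` (effects `&`-joined, carriers
comma-joined); VCF input expects an ANN-style INFO field
`allele|terms|gene|transcript|canonical`.

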