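# egobp

Biocultural modelling of blood pressure from egocentric social networks and
ACE haplotypes.

Hypertension has both genetic and sociocultural risk factors, and studies
that carry only one data type routinely miss how the two interact.  `egobp`
implements, as a tested and reusable pipeline, the analysis design of a
community-based study of blood pressure in African-American adults: each
participant (*ego*) names exactly 30 people (*alters*), rates every alter
pair's likelihood of contact on a 1–5 scale, and is genotyped at three
markers of the angiotensin-I-converting-enzyme gene (*ACE*): rs4313, rs4337
and the intron-16 *Alu* insertion.  The pipeline turns these raw tables into
linear models of systolic and diastolic blood pressure (SBP/DBP) that
combine covariates, haplotypes and network structure.

It is aimed at biocultural / genetic-epidemiology researchers who want to
reuse or stress-test this design — and, because the original field data are
not deposited, it ships a calibrated synthetic-cohort generator so every
stage is runnable and testable end to end.

## What it computes

**Ego-network measures** (per participant, from the 435 pair ratings; pairs
rated ≥ 4 are ties):

* mean betweenness — average over the 30 alters of unnormalized betweenness
  centrality, B(v) = Σ_{s<t} σ_st(v)/σ_st (fractional shortest-path
  counting, Brandes accumulation);
* mean distance — average geodesic distance over reachable alter pairs;
* % family — share of the 30 alters who are blood family, family by
  marriage, or a spouse;
* % of the three central positions (most between, most close by harmonic
  closeness, most distant by farness) occupied by family.

**Haplotypes** — Excoffier–Slatkin EM estimates frequencies of the four
block-1 haplotypes (hap1 T-G-N, hap2 C-G-N, hap3 T-G-I, hap4 T-C-I) from
unphased genotypes, phases each individual (posterior-best diplotype), and
emits an additive dosage coding with hap1 as the reference group.  Pairwise
D′/r² and a contiguous-run D′ ≥ 0.8 block rule are included.

**Phenotype** — BP per participant is the mean of the last two of three
readings; antihypertensive-medication users get +10 mmHg (SBP) / +5 mmHg
(DBP).  The four network measures are square-root transformed before
modelling.

**Models** — for each response, OLS fits of the base model (age, BMI,
sex[male = 1, female = 2]), genetic model (+ haplotype dosages as one
block), network model (+ measures surviving selection), and the optimal
model built by sequential forward selection: a candidate is kept only if it
*lowers* AIC and *raises* adjusted R².  Nested-ANOVA F tests compare models,
Bonferroni α = 0.05/5 = 0.01 corrects the five predictor families, and
Tukey–Kramer HSD contrasts SBP/DBP across haplotype groups.

## Worked example

```bash
egobp simulate --out bundle --seed 42 --n 138     # synthetic study, field scale
egobp validate bundle
egobp pipeline bundle --out run
```

With seed 42 at n = 138 the run prints/writes (`run/model_fits.json`,
`run/report.md`):

```
SBP optimal terms: age, bmi, sex, dosage_hap2, dosage_hap3, dosage_hap4,
                   sqrt_pct_central_family
  adjusted R2: base 0.251 -> genetic 0.303 -> network 0.269 -> optimal 0.327
  AIC:         base 1188.6 -> optimal 1177.7
  coefficients: age 0.32, bmi 1.05, sex -16.43, hap2 -13.46, hap3 -25.05,
                hap4 -9.70, sqrt(% central family) 9.57
DBP optimal terms: age, bmi, sex, dosage_hap2, dosage_hap3, dosage_hap4
  adjusted R2: base 0.085 -> optimal 0.177
```

Read: adding haplotypes and the family-centrality measure to the covariates
raises explained SBP variance from 25% to 33% and lowers AIC by ~11; all
three non-reference haplotypes shift SBP downward relative to hap1
(carrying hap4 lowers expected SBP by ~10 mmHg per copy), while having
family in the network's central positions raises it.  At this sample size
selection is noisy — which terms survive varies from study to study; the
full audit of every add/keep decision is in `run/selection_trace.json`.

The generating truth for any synthetic bundle is in `bundle/truth.json`, so
you can compare fitted coefficients against the simulated ones.

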