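# mrscore

Weighted allele-score Mendelian randomization for case–control consortia,
with cluster-robust reduced-form models, left-truncated survival analysis,
and Wald rescaling to phenotype units.

## The problem

Observational associations between anthropometric traits (height, body
mass index) and cancer risk or mortality are vulnerable to confounding and
reverse causation. Mendelian randomization sidesteps both by using genetic
variants as instruments: alleles are assigned at conception, so a *genetic
risk score* — a weighted sum of trait-increasing allele dosages,
S_i = Σ_j w_j d_ij with GWAS effect sizes as weights w_j — is associated
with the outcome only through the trait it proxies (absent pleiotropy and
population structure).

`mrscore` implements the full analysis pipeline for a multi-study
case–control consortium with partial follow-up:

- **Instrument construction** — read GWAS weight tables and allele dosages
  (VCF `DS` field or TSV matrices), harmonize coded alleles to effect
  alleles (d → 2−d flips), build weighted/unweighted scores, standardize to
  SD units, form quintiles, and split instruments into independent halves.
- **Instrument diagnostics** — first-stage R² and F = (n−2)R²/(1−R²);
  closed-form power for a binary outcome,
  power = Φ(√(N·K(1−K)·R²)·|ln OR| − z_{1−α/2}); genotype principal
  components; a confounder scan of the score against measured covariates.
- **Reduced-form models** — logistic odds ratios of disease per score SD
  with cluster-robust (study-level sandwich) standard errors, overall and
  by tumour stage (localized/advanced) and grade (Gleason ≤6 / ≥7);
  top-vs-bottom quintile contrasts; per-study fixed-effect meta-analysis
  with Cochran's Q and I²; case-only subtype heterogeneity tests.
- **Survival models** — Cox proportional hazards on the age scale with
  delayed entry at diagnosis age (left truncation), Breslow ties,
  cause-specific censoring, cluster-robust variance, and a
  Grambsch–Therneau proportional-hazards check.
- **Between-estimate inference** — the Altman–Bland z-test
  z = (b₁−b₂)/√(se₁²+se₂²) for subtype and split-instrument heterogeneity,
  and Wald rescaling b → b/(√R²·σ_unit) to express per-score-SD estimates
  per phenotype SD or per natural unit (e.g. kg/m²).
- **Synthetic consortium generator** — a first-class, seeded simulator of
  a multi-study case–control consortium (Hardy–Weinberg genotypes with
  per-study allele-frequency drift, calibrated first-stage R², logistic
  disease risk with study intercepts, grade/stage-specific effects,
  competing exponential hazards, exact missing-follow-up fractions, and a
  pleiotropy switch), so every stage is testable end to end without
  restricted data.

The regression stages follow the statsmodels idiom: `ClusterLogit` /
`LeftTruncatedCox` model objects whose `fit()` returns a results object
with `params`, `bse`, `conf_int()`, `pvalues` and `summary()`.

## Worked example

```python
import mrscore as m

data = m.simulate_consortium(m.SimulationSpec(seed=42))   # 6 studies, 3,000 men
w = data.weights_for("height")
score = m.standardize(m.build_score(m.harmonize(data.panel, w), w))

ph = data.cohort.data.set_index("subject_id")["height"]
z = (ph - ph.mean()) / ph.std(ddof=1)
diag = m.first_stage(score.as_series().loc[z.index].to_numpy(), z.to_numpy())

est = m.reduced_form_or(data.cohort, score)
hr = m.cox_effect(m.SurvivalSpec(event="disease-specific",
                                 case_subset="low_grade"), data.cohort, score)
rescaled = m.wald_rescale(hr, m.RescaleSpec(r2=diag.r2))
```

prints, via the obvious f-strings:

```
first stage: n=3000 R2=0.0760 F=246.5
reduced form OR per score SD: 0.958 (0.848, 1.082) p=0.40
low-grade disease-specific HR: 1.217 (0.780, 1.901) p=0.308, events=39
per height SD after rescaling: 2.041 (0.405, 10.285)
```

The first stage shows a strong instrument (realized R² near the 6.31%
target, F ≫ 10). The reduced-form OR per score SD is compatible with no
effect at this desk scale. The low-grade hazard ratio is the per-score-SD
estimate; dividing its log by √R² re-expresses it per SD of height — with
39 events the rescaled interval is wide, which is exactly why the real
analysis needed tens of thousands of cases. At the published consortium
scale the closed-form power is

```python
m.mr_power_binary(m.PowerInput(20848, 20214, 0.0631, 1.12))   # 0.822 -> "82%"
```

The whole analysis also runs as a CLI:

```bash
mrscore --seed 42 --out-dir out all     # report.tsv/report.json + manifest
mrscore --out-dir out report
```

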