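# Methods

## Scores and harmonization

The instrument for each phenotype is a weighted allele score
S_i = Σ_j w_j d_ij over variants j with published per-allele effects w_j
(phenotype units per effect allele) and imputed dosages d_ij ∈ [0, 2].
Dosages are harmonized before scoring: where the panel's coded allele is
the weight table's *other* allele the dosage is flipped to 2−d; a coded
allele matching neither weight allele is a hard error. Strand-ambiguous
pairs (A/T, C/G) carry no strand information in dosage data, so they are
harmonized by allele label with a warning; `drop_ambiguous=True` removes
them instead. Weight variants absent from the panel are dropped with a
warning, and more than 20% absent is an error — past that point the score
no longer measures the published instrument. Missing per-subject dosages
are mean-imputed by default (≈ 2× allele frequency, preserving score
comparability across subjects), with a drop-subject alternative.

Scores are standardized to mean 0, SD 1 (n−1 divisor) over the full
analysis sample by default; all effects are reported per score SD.
A controls-only standardization sample is available by configuration.
Quintile cut points are the 20/40/60/80th percentiles of the same sample,
ties assigned to the lower group (deterministic and order-independent).
The TSV dosage format annotates the header as `variant:coded:other` so
allele orientation survives a write/read round trip; bare-id headers are
accepted and treated, with a warning, as already effect-allele coded.

## Instrument diagnostics and power

The first stage is the simple linear regression of the standardized
phenotype on the standardized score: R² is the squared correlation and
F = (n−2)R²/(1−R²). The diagnostics intentionally report this
single-predictor F (no covariates), so F and R² always satisfy that
identity. Power for the reduced-form test of a binary outcome uses the
closed form

    power = Φ( √(N·K·(1−K)·R²) · |ln OR_alt| − z_{1−α/2} ),

with N the total sample, K the case fraction, R² the phenotype variance
explained by the score and OR_alt the per-phenotype-SD alternative. At
R² = 0 the formula degenerates to α/2 and a warning is emitted. Population
structure is summarized by the top-k principal components of the
column-centered dosage matrix (SVD; axes signed so the largest-magnitude
variant loading is positive), computed on the instrument variants the
panel provides; an externally computed PC file can be merged instead.

## Regression stages

All case–control contrasts are *reduced-form* logistic regressions of
case status on the standardized score (controls always the comparison
group), with the variance estimated by the cluster sandwich

    V = A⁻¹ ( Σ_g s_g s_gᵀ ) A⁻¹ · G/(G−1) · (N−1)/(N−k),

where A is the observed information, s_g the score summed over study g,
and the trailing small-sample factor (switchable) follows the convention
of the major survey-statistics packages. The logistic MLE itself is the
Newton fit of statsmodels' `Logit` (score tolerance 1e-8, 50 iterations);
perfect separation and non-convergence raise named errors.

**Reference distribution.** Clustered fits are tested and intervalled
against a Student t with G−1 degrees of freedom rather than the normal.
With ~20 clusters the sandwich variance is itself noisy and
normal-referenced Wald tests over-reject (we measure ~8–9% at a nominal
5% across seeded null replicates; the t reference brings every stage into
the 3–8% band). Unclustered fits use the normal reference, and all CIs
from *printed* tables use z = 1.959964 exactly so published intervals
round-trip bit-for-bit.

Subtype analyses select localized/advanced (TNM T1–T2 vs T3–T4) or
low/high grade (Gleason ≤6 vs ≥7) cases; unknown-subtype cases stay in
the "all cancers" analysis and drop from subtype analyses. Case-only
heterogeneity regresses the subtype indicator on the score among cases,
cluster-robust; its p is the incidence-heterogeneity p. Between-study
heterogeneity refits each study separately (unclustered), pools by
fixed-effect inverse variance, and reports Q = Σ w_g(b_g−b̄)² and
I² = max(0, (Q−(G−1))/Q)·100.

Survival runs among cases on the age scale: entry at diagnosis age, exit
at death or final follow-up, so risk sets at an event age contain only
cases already diagnosed and still under observation (left truncation).
The Cox partial likelihood uses Breslow tie handling and is maximized by
Newton with step-halving; the fit is implemented in-package because the
combination of delayed entry, Breslow ties and the sandwich factor above
is not available together elsewhere, and it is cross-checked in the test
suite against both a grid-search maximizer of the partial likelihood and
lifelines (whose Efron weights coincide with Breslow in the absence of
ties). Robust variance uses Lin–Wei score residuals summed by study.
Disease-specific analyses censor other-cause deaths. Cases missing either
follow-up age are excluded and counted (`n_excluded`). The
proportional-hazards check is the Grambsch–Therneau association of
Schoenfeld residuals with event-time rank, per covariate and globally.

The Altman–Bland comparison of two independent estimates is
z = (b₁−b₂)/√(se₁²+se₂²) with a two-sided normal p; standard errors may
be reconstructed from printed CIs as (ln hi − ln lo)/(2·1.959964).

Wald rescaling divides the log estimate (and its CI bounds on the log
scale) by √R²·σ_unit: for jointly standardized score and phenotype the
first-stage coefficient equals the correlation √R², and σ_unit converts
phenotype SDs to natural units (σ_unit = 3.5 kg/m² for per-kg/m² BMI
effects; 1 for per-SD effects). R² and σ_unit are treated as known
constants — no uncertainty is propagated — matching how such rescalings
are conventionally reported. In the instrument-split analysis each half
is rescaled by its own realized √R² so the two estimates share the
per-phenotype-SD scale before the Altman–Bland comparison; this is a
package choice, flagged in the estimate labels, since each half explains
a different fraction of the phenotype.

## The synthetic consortium

The generator produces the structure the analysis assumes, not a
population-genetics model:

- **Variants**: distinct rs-style ids; weights log-normal
  (σ = 0.9 on the log scale) so a few variants dominate, mimicking the
  FTO-like tail of real anthropometric instruments; allele pairs drawn
  uniformly (so a realistic minority is strand-ambiguous).
- **Genotypes**: Hardy–Weinberg binomial(2, f) draws; per-study
  frequencies shifted on the logit scale by N(0, drift), default
  drift 0.05, giving mild population structure for the PC machinery;
  `noise` (default 0.05) blurs integer genotypes toward 2f with a small
  Gaussian jitter and clips to [0, 2], an imputation-quality proxy.
- **Phenotypes**: genetic value plus Gaussian noise with variance
  var(g)(1−R²)/R², so the population first-stage R² equals the target —
  defaults 0.0631 (height-like) and 0.0146 (BMI-like), the strengths of
  the real instruments.
- **Disease**: logistic on the standardized phenotypes with per-study
  intercepts (baseline prevalence 0.25, intercept SD 0.25) and per-SD
  log-ORs defaulting to the published point estimates (OR 0.99 height,
  0.98 BMI). Latent tumour grade and stage are assigned to every diseased
  subject with phenotype-dependent odds; labels are masked to "unknown"
  for 18%/17% of cases, mirroring the real subtype attrition.
- **Survival**: from a N(65, 8) diagnosis age, competing exponential
  hazards for disease-specific (grade-dependent baseline 0.012/0.035 per
  year) and other-cause (0.02 per year) death with grade-specific per-SD
  log-HRs (defaults emulate the published pattern: height acts on
  disease-specific death in low-grade disease, BMI on other-cause death),
  and uniform administrative censoring at 1–15 years.
- **Ascertainment**: each study retains its specified case and control
  counts from a source population oversampled 6× (sized to survive the
  low tail of the study-intercept distribution); an exact
  round(fraction × cases) of cases get both follow-up ages blanked,
  default 5,357/20,848 — so a 20,848-case cohort leaves exactly 15,491
  analyzable.
- **Pleiotropy switch**: a direct disease log-OR through the first half
  of a phenotype's variants (standardized sub-score), off by default;
  the positive control for the instrument-split sensitivity analysis.

Everything is a pure function of (spec, seed) via a spawned SeedSequence;
identical seeds give byte-identical fixture files. What the generator
does *not* emulate: linkage disequilibrium between instrument variants
(the real height variants were selected to be in linkage equilibrium),
screening-driven detection bias, genotyping batch effects, and
non-exponential hazard shapes. Passing tests therefore demonstrate the
statistical machinery under the stated generative assumptions, not
robustness to those real-data features.

## Experiment sizes in the test suite

Monte-Carlo tests are sized so their bands are informative at desk scale:
null-calibration experiments use 22 studies of 40+40 (matching the real
consortium's cluster count, which is what governs sandwich calibration)
over 400 seeded replicates (≈1% MC error on a 5% rate); coverage and
sign-consistency experiments use 100–4,800 subjects per replicate chosen
so the effect's Wald z exceeds 3; the grade-specific hazard recovery uses
case-heavy ascertainment (250 cases + 50 controls per study, 10×
oversampling) to accumulate events. The full default pipeline (6 studies,
3,000 subjects, 70 variants) runs in ~2.5 s.

## Numerical conventions and edge cases

- Logistic convergence: max score component < 1e-8; Cox: max gradient
  < 1e-8 with step-halving; |β| > 30 (logit) or > 50 (Cox) raises a
  separation error naming the exposure.
- The linear predictor is max-shifted before exponentiation in the Cox
  sweep (Breslow terms are invariant to the shift).
- A perfect first-stage fit reports F = +inf with a warning rather than
  an error.
- Quintile ties go to the lower group; an error is raised below 5
  distinct values.
- `se_from_ci(x, x) = 0`; downstream consumers that need a positive SE
  must guard the degenerate case.
- Cases with unknown grade/stage use their *latent* grade for hazard
  generation in the simulator (the label, not the biology, is missing).

## Known limitations

- The case-only heterogeneity test is the two-subtype logistic form;
  a polytomous (case/control × subtype) model is a noted alternative.
- Competing risks are handled by cause-specific censoring, not
  subdistribution (Fine–Gray) hazards.
- Ratio-of-coefficients MR with delta-method or Fieller intervals, and
  pleiotropy-robust estimators (MR-Egger, weighted median), are out of
  scope; the rescaling treats R² as a known constant.
- PCs are computed from the instrument variants only, which understates
  genome-wide structure; supply external PCs where available.
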