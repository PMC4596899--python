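"""Synthetic multi-study case-control consortium generator.

Emulates the statistical structure the downstream analysis assumes: a
consortium of case-control studies genotyped at two sets of instrument
variants (height-like and BMI-like), phenotypes driven by weighted allele
sums with a calibrated first-stage R², disease risk following a logistic
model on the phenotype SD scale with study intercepts, tumour grade and
stage assigned with phenotype-dependent odds, and post-diagnosis survival
from competing exponential hazards (disease-specific vs other-cause) on
the age scale with administrative censoring, left truncation at the
diagnosis age, and a configurable fraction of cases missing both
follow-up ages.

Genetic effects on disease and death act only through the phenotypes by
default; a pleiotropy switch adds a direct effect of half of a
phenotype's variants, as a positive control for the instrument-split
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .types import CohortTable, DosagePanel, MrscoreError, VariantWeight, WeightTable

NUCS = np.array(list("ACGT"))

LN = math.log


def _default_n_variants() -> dict:
    return {"height": 50, "bmi": 20}


def _default_target_r2() -> dict:
    # variance explained by the real scores in the phenotype data
    return {"height": 0.0631, "bmi": 0.0146}


def _default_disease_logor() -> dict:
    return {"height": LN(0.99), "bmi": LN(0.98)}


def _default_grade_high_logor() -> dict:
    # phenotype effect on P(high grade | case)
    return {"height": LN(1.00 / 0.99), "bmi": LN(1.00 / 0.97)}


def _default_stage_advanced_logor() -> dict:
    return {"height": LN(0.96 / 1.00), "bmi": LN(1.01 / 0.98)}


def _default_hr_disease_death() -> dict:
    # per-phenotype-SD log-HR of disease-specific death, by tumour grade
    return {
        "height": {"low": LN(1.13), "high": LN(0.97)},
        "bmi": {"low": LN(0.95), "high": LN(1.05)},
    }


def _default_hr_other_death() -> dict:
    return {
        "height": {"low": 0.0, "high": 0.0},
        "bmi": {"low": LN(1.15), "high": LN(1.02)},
    }


def _default_pleiotropy_logor() -> dict:
    return {"height": 0.0, "bmi": 0.0}


def _default_base_hazard_disease() -> dict:
    return {"low": 0.012, "high": 0.035}


@dataclass
class SimulationSpec:
    """Generative parameters of the synthetic consortium.

    Defaults are desk scale: 6 studies of 250 cases + 250 controls, 50
    height-like and 20 BMI-like variants, first-stage R² targets matching
    the strengths of the real instruments.
    """

    n_studies: int = 6
    n_cases_per_study: int = 250
    n_controls_per_study: int = 250
    n_variants: dict = field(default_factory=_default_n_variants)
    freq_range: tuple = (0.1, 0.9)
    target_r2: dict = field(default_factory=_default_target_r2)
    disease_logor: dict = field(default_factory=_default_disease_logor)
    grade_high_logor: dict = field(default_factory=_default_grade_high_logor)
    stage_advanced_logor: dict = field(default_factory=_default_stage_advanced_logor)
    hr_disease_death: dict = field(default_factory=_default_hr_disease_death)
    hr_other_death: dict = field(default_factory=_default_hr_other_death)
    pleiotropy_logor: dict = field(default_factory=_default_pleiotropy_logor)
    confounder_phenotype_sd: float = 0.0   # confounder effect on each phenotype
    confounder_disease_logor: float = 0.0  # and on disease risk
    drift: float = 0.05                    # per-study allele-frequency drift (logit SD)
    noise: float = 0.05                    # imputation-style dosage blur
    missing_followup_frac: float = 5357 / 20848
    baseline_prevalence: float = 0.25
    study_intercept_sd: float = 0.25
    grade_known_frac: float = 0.82
    stage_known_frac: float = 0.83
    base_grade_high: float = 0.48          # P(high grade) at phenotype means
    base_stage_advanced: float = 0.25
    diagnosis_age_mean: float = 65.0
    diagnosis_age_sd: float = 8.0
    base_hazard_disease: dict = field(default_factory=_default_base_hazard_disease)
    base_hazard_other: float = 0.02
    max_followup_years: float = 15.0
    # source-population inflation; sized so the diseased pool per study
    # survives the low tail of the study-intercept distribution
    oversample: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p, r2 in self.target_r2.items():
            if not (0 < r2 < 1):
                raise MrscoreError(f"target_r2[{p!r}] must be in (0, 1)")
        lo, hi = self.freq_range
        if not (0 < lo < hi < 1):
            raise MrscoreError("freq_range must satisfy 0 < lo < hi < 1")
        if self.n_cases_per_study <= 0 or self.n_controls_per_study <= 0:
            raise MrscoreError("case and control counts must be positive")
        if not (0 <= self.missing_followup_frac < 1):
            raise MrscoreError("missing_followup_frac must be in [0, 1)")
        self.seed = int(self.seed)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.n_variants)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["freq_range"] = list(self.freq_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationSpec":
        d = dict(d)
        if "freq_range" in d:
            d["freq_range"] = tuple(d["freq_range"])
        return cls(**d)


def simulate_weights(
    m: int,
    seed: int,
    phenotype_tag: str = "custom",
    weight_scale: float = 0.05,
    skew: float = 0.9,
) -> WeightTable:
    """m variants with distinct rs-style ids and right-skewed positive weights.

    A log-normal weight distribution makes a few variants dominate the
    score (an FTO-like tail), which the split analyses rely on.
    """
    if m < 1:
        raise MrscoreError("need at least one variant")
    rng = np.random.default_rng(seed)
    numbers = rng.choice(9_000_000, size=m, replace=False) + 1_000_000
    weights = rng.lognormal(mean=math.log(weight_scale), sigma=skew, size=m)
    variants = []
    for i in range(m):
        e, o = rng.choice(4, size=2, replace=False)
        variants.append(
            VariantWeight(
                variant_id=f"rs{numbers[i]}",
                effect_allele=str(NUCS[e]),
                other_allele=str(NUCS[o]),
                weight=float(weights[i]),
                phenotype_tag=phenotype_tag,
            )
        )
    return WeightTable(variants)


def simulate_dosages(
    n_subjects,
    weights: WeightTable,
    freqs: np.ndarray,
    drift: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> DosagePanel:
    """Hardy-Weinberg genotypes, optionally drifted per study and blurred.

    ``n_subjects`` may be an int (one study) or a list of per-study sizes;
    subjects are emitted study by study. Per-study allele frequencies are
    the base frequencies shifted on the logit scale by N(0, drift).
    ``noise`` blurs integer genotypes toward the expected dosage 2f (an
    imputation-quality proxy); dosages are clipped to [0, 2].
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise MrscoreError("allele frequencies must be in (0, 1)")
    if len(freqs) != len(weights):
        raise MrscoreError("need one frequency per variant")
    sizes = [n_subjects] if np.isscalar(n_subjects) else list(n_subjects)
    rng = np.random.default_rng(seed)
    m = len(weights)
    blocks = []
    for ns in sizes:
        f_s = expit(logit(freqs) + rng.normal(0.0, drift, size=m)) if drift > 0 else freqs
        g = rng.binomial(2, f_s, size=(ns, m)).astype(float)
        if noise > 0:
            g = (1 - noise) * g + noise * (2 * f_s) + rng.normal(0.0, noise / 2, size=g.shape)
            g = np.clip(g, 0.0, 2.0)
        blocks.append(g)
    D = np.vstack(blocks)
    subject_ids = [f"S{i:06d}" for i in range(1, D.shape[0] + 1)]
    df = pd.DataFrame(D, index=subject_ids, columns=weights.variant_ids)
    coded = {v.variant_id: v.effect_allele for v in weights}
    other = {v.variant_id: v.other_allele for v in weights}
    return DosagePanel(df, coded, other)


def simulate_phenotype(
    panel: DosagePanel, weights: WeightTable, target_r2: float, seed: int = 0
) -> np.ndarray:
    """Phenotype = genetic value + Gaussian noise calibrated to target R².

    The genetic value is g_i = sum_j w_j d_ij; noise variance is
    var(g) (1 - R²) / R², so the population fraction of phenotype variance
    attributable to the score equals ``target_r2``.
    """
    if not (0 < target_r2 < 1):
        raise MrscoreError("target_r2 must be in (0, 1)")
    D = panel.dosages[weights.variant_ids].to_numpy()
    g = D @ weights.weights
    var_g = float(np.var(g, ddof=1))
    if var_g <= 0:
        raise MrscoreError("degenerate genetic value (zero variance)")
    noise_sd = math.sqrt(var_g * (1 - target_r2) / target_r2)
    rng = np.random.default_rng(seed)
    return g + rng.normal(0.0, noise_sd, size=len(g))


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_outcomes(
    phenotypes: pd.DataFrame,
    study_ids: np.ndarray,
    spec: SimulationSpec,
    seed: int = 0,
    pleiotropy_lp: np.ndarray | None = None,
    confounder: np.ndarray | None = None,
) -> CohortTable:
    """Disease, subtype, survival and ascertainment for a source population.

    ``phenotypes`` holds raw phenotype values per subject (standardized
    internally before the log-ORs apply); ``study_ids`` assigns each source
    subject to a study. Case-control ascertainment retains the spec's
    per-study counts; an error advises a larger source population when a
    study's diseased pool is too small.
    """
    rng = np.random.default_rng(seed)
    n = len(phenotypes)
    z = {p: _standardize(phenotypes[p].to_numpy()) for p in phenotypes.columns}
    studies = pd.unique(study_ids)
    alpha = dict(
        zip(studies, logit(spec.baseline_prevalence)
            + rng.normal(0.0, spec.study_intercept_sd, size=len(studies)))
    )
    lp = np.array([alpha[s] for s in study_ids], dtype=float)
    for p, zp in z.items():
        lp += spec.disease_logor.get(p, 0.0) * zp
    if pleiotropy_lp is not None:
        lp += pleiotropy_lp
    if confounder is not None:
        lp += spec.confounder_disease_logor * confounder
    disease = rng.random(n) < expit(lp)

    # latent grade/stage for every diseased subject; labels partially masked
    lp_grade = logit(spec.base_grade_high) + sum(
        spec.grade_high_logor.get(p, 0.0) * z[p] for p in z
    )
    lp_stage = logit(spec.base_stage_advanced) + sum(
        spec.stage_advanced_logor.get(p, 0.0) * z[p] for p in z
    )
    latent_high = rng.random(n) < expit(lp_grade)
    latent_adv = rng.random(n) < expit(lp_stage)

    # competing exponential hazards on the age scale, from diagnosis age
    age_dx = np.clip(
        rng.normal(spec.diagnosis_age_mean, spec.diagnosis_age_sd, size=n), 40.0, 90.0
    )
    base_d = np.where(latent_high, spec.base_hazard_disease["high"],
                      spec.base_hazard_disease["low"])
    lhr_d = np.zeros(n)
    lhr_o = np.zeros(n)
    for p, zp in z.items():
        hr_d = spec.hr_disease_death.get(p, {})
        hr_o = spec.hr_other_death.get(p, {})
        lhr_d += np.where(latent_high, hr_d.get("high", 0.0), hr_d.get("low", 0.0)) * zp
        lhr_o += np.where(latent_high, hr_o.get("high", 0.0), hr_o.get("low", 0.0)) * zp
    t_disease = rng.exponential(1.0 / (base_d * np.exp(lhr_d)))
    t_other = rng.exponential(1.0 / (spec.base_hazard_other * np.exp(lhr_o)))
    t_censor = rng.uniform(1.0, spec.max_followup_years, size=n)
    t = np.minimum.reduce([t_disease, t_other, t_censor])
    died = (t < t_censor).astype(int)
    cause = np.where(
        died == 0, "alive", np.where(t_disease <= t_other, "disease", "other")
    )

    # per-study case-control ascertainment
    keep = []
    for s in studies:
        in_s = np.where(study_ids == s)[0]
        cases_s = in_s[disease[in_s]]
        ctrls_s = in_s[~disease[in_s]]
        if len(cases_s) < spec.n_cases_per_study:
            raise MrscoreError(
                f"study {s}: only {len(cases_s)} diseased subjects for "
                f"{spec.n_cases_per_study} requested cases — enlarge the source "
                "population (raise oversample or baseline_prevalence)"
            )
        if len(ctrls_s) < spec.n_controls_per_study:
            raise MrscoreError(
                f"study {s}: control pool too small — enlarge the source population"
            )
        keep.append(rng.choice(cases_s, size=spec.n_cases_per_study, replace=False))
        keep.append(rng.choice(ctrls_s, size=spec.n_controls_per_study, replace=False))
    idx = np.sort(np.concatenate(keep))

    df = pd.DataFrame(
        {
            "subject_id": phenotypes.index[idx],
            "study_id": np.asarray(study_ids)[idx],
            "case": disease[idx].astype(int),
        }
    )
    is_case = df["case"] == 1
    grade = np.where(latent_high[idx], "high", "low")
    stage = np.where(latent_adv[idx], "advanced", "localized")
    mask_g = rng.random(len(idx)) > spec.grade_known_frac
    mask_s = rng.random(len(idx)) > spec.stage_known_frac
    df["grade_class"] = np.where(is_case & ~mask_g, grade, "unknown")
    df["stage_class"] = np.where(is_case & ~mask_s, stage, "unknown")
    df["age_entry"] = np.where(is_case, age_dx[idx], np.nan)
    df["age_exit"] = np.where(is_case, age_dx[idx] + t[idx], np.nan)
    df["died"] = np.where(is_case, died[idx], 0)
    df["death_cause"] = np.where(is_case, cause[idx], "alive")

    # blank both follow-up ages for an exact count of cases
    case_pos = np.where(is_case.to_numpy())[0]
    n_miss = int(round(spec.missing_followup_frac * len(case_pos)))
    if n_miss:
        blank = rng.choice(case_pos, size=n_miss, replace=False)
        df.loc[blank, ["age_entry", "age_exit"]] = np.nan
        df.loc[blank, "died"] = 0
        df.loc[blank, "death_cause"] = "alive"

    for p in phenotypes.columns:
        df[p] = phenotypes[p].to_numpy()[idx]
    # benign covariates, independent of the genotypes, for the confounder scan
    df["diabetes"] = (rng.random(len(idx)) < 0.07).astype(int)
    df["age_recruit"] = np.clip(rng.normal(62.0, 7.0, size=len(idx)), 40, 90)
    covars = ["diabetes", "age_recruit"]
    if confounder is not None:
        df["confounder"] = confounder[idx]
        covars.append("confounder")
    return CohortTable(df, phenotype_cols=list(phenotypes.columns), covariate_cols=covars)


@dataclass
class ConsortiumData:
    panel: DosagePanel
    weights: WeightTable
    cohort: CohortTable

    def weights_for(self, phenotype: str) -> WeightTable:
        ids = [v.variant_id for v in self.weights if v.phenotype_tag == phenotype]
        return self.weights.subset(ids)


def simulate_consortium(spec: SimulationSpec, out_dir=None) -> ConsortiumData:
    """End-to-end synthetic consortium: panel + weights + ascertained cohort.

    With ``out_dir`` set, also writes the fixture files (weights.tsv,
    dosages.tsv, cohort.tsv) in the package's standard formats.
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(6 + len(spec.n_variants)) % (2**31)

    tables = []
    for i, (pheno, m) in enumerate(spec.n_variants.items()):
        tables.append(simulate_weights(int(m), int(seeds[i]), phenotype_tag=pheno))
    all_weights = WeightTable([v for t in tables for v in t])

    n_pheno = len(spec.n_variants)
    rng_freq = np.random.default_rng(int(seeds[n_pheno]))
    lo, hi = spec.freq_range
    freqs = rng_freq.uniform(lo, hi, size=len(all_weights))

    per_study = math.ceil(
        (spec.n_cases_per_study + spec.n_controls_per_study) * spec.oversample
    )
    sizes = [per_study] * spec.n_studies
    panel = simulate_dosages(
        sizes, all_weights, freqs, drift=spec.drift, noise=spec.noise,
        seed=int(seeds[n_pheno + 1]),
    )
    study_ids = np.repeat([f"study{j+1}" for j in range(spec.n_studies)], per_study)

    rng_conf = np.random.default_rng(int(seeds[n_pheno + 2]))
    confounder = (
        rng_conf.normal(size=panel.n_subjects)
        if (spec.confounder_phenotype_sd or spec.confounder_disease_logor)
        else None
    )

    phen = {}
    for i, (pheno, m) in enumerate(spec.n_variants.items()):
        w_p = all_weights.subset(tables[i].variant_ids)
        vals = simulate_phenotype(panel, w_p, spec.target_r2[pheno],
                                  seed=int(seeds[n_pheno + 3]) + i)
        if confounder is not None and spec.confounder_phenotype_sd:
            vals = vals + spec.confounder_phenotype_sd * np.std(vals, ddof=1) * confounder
        phen[pheno] = vals
    phenotypes = pd.DataFrame(phen, index=panel.dosages.index)

    pleio_lp = None
    if any(v != 0.0 for v in spec.pleiotropy_logor.values()):
        pleio_lp = np.zeros(panel.n_subjects)
        for i, (pheno, m) in enumerate(spec.n_variants.items()):
            b = spec.pleiotropy_logor.get(pheno, 0.0)
            if b == 0.0:
                continue
            ids = tables[i].variant_ids[: len(tables[i]) // 2]
            direct = panel.dosages[ids].to_numpy() @ all_weights.subset(ids).weights
            pleio_lp += b * _standardize(direct)

    cohort = simulate_outcomes(
        phenotypes, study_ids, spec, seed=int(seeds[n_pheno + 4]),
        pleiotropy_lp=pleio_lp, confounder=confounder,
    )
    panel_sel = panel.subset_subjects(cohort.data["subject_id"])
    data = ConsortiumData(panel_sel, all_weights, cohort)

    if out_dir is not None:
        from pathlib import Path
        from . import io as mio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_weights(all_weights, out / "weights.tsv")
        mio.write_dosages(panel_sel, out / "dosages.tsv")
        mio.write_cohort(cohort, out / "cohort.tsv")
    return data
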