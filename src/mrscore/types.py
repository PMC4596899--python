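"""Domain containers for allele-score Mendelian randomization.

The analysis moves three kinds of data around: per-variant GWAS weights
(the instrument definition), subject-by-variant allele dosages in [0, 2]
(the genotypes), and a per-subject cohort table (case status, tumour
grade/stage, follow-up ages, phenotypes, covariates, study membership).
Association results are carried as :class:`EffectEstimate` objects on the
log odds-ratio / log hazard-ratio scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

NUCLEOTIDES = frozenset("ACGT")

#: allele pairs that cannot be disambiguated by strand (A/T and C/G)
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

#: 95% normal quantile used for every confidence interval in the package
Z95 = 1.959964

GRADE_LEVELS = ("low", "high", "unknown")
STAGE_LEVELS = ("localized", "advanced", "unknown")
DEATH_CAUSES = ("disease", "other", "alive")


class MrscoreError(ValueError):
    """Base class for validation and fitting errors raised by mrscore."""


@dataclass(frozen=True)
class VariantWeight:
    """One instrument variant: its effect allele and per-allele weight.

    ``weight`` is in phenotype units per effect allele (e.g. cm of height
    per height-increasing allele) as published by the discovery GWAS.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    weight: float
    phenotype_tag: str = "custom"

    def __post_init__(self) -> None:
        if self.effect_allele not in NUCLEOTIDES:
            raise MrscoreError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} is not a nucleotide"
            )
        if self.other_allele not in NUCLEOTIDES:
            raise MrscoreError(
                f"{self.variant_id}: other allele {self.other_allele!r} is not a nucleotide"
            )
        if self.effect_allele == self.other_allele:
            raise MrscoreError(f"{self.variant_id}: effect and other allele are identical")
        if not math.isfinite(self.weight):
            raise MrscoreError(f"{self.variant_id}: weight {self.weight!r} is not finite")

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in AMBIGUOUS_PAIRS


class WeightTable:
    """Ordered collection of :class:`VariantWeight` with unique ids."""

    def __init__(self, variants: Iterable[VariantWeight]):
        self.variants: list[VariantWeight] = list(variants)
        if not self.variants:
            raise MrscoreError("weight table is empty")
        seen: set[str] = set()
        for v in self.variants:
            if v.variant_id in seen:
                raise MrscoreError(f"duplicate variant id in weight table: {v.variant_id}")
            seen.add(v.variant_id)
        self._by_id = {v.variant_id: v for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def __getitem__(self, variant_id: str) -> VariantWeight:
        return self._by_id[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightTable) and self.variants == other.variants

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)

    def subset(self, variant_ids: Sequence[str]) -> "WeightTable":
        return WeightTable(self._by_id[i] for i in variant_ids)

    def scaled(self, c: float) -> "WeightTable":
        return WeightTable(replace(v, weight=v.weight * c) for v in self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "weight": self.weights,
                "phenotype_tag": [v.phenotype_tag for v in self.variants],
            }
        )


class DosagePanel:
    """Subject-by-variant expected allele counts in [0, 2].

    ``dosages`` is a DataFrame indexed by subject id with one column per
    variant. ``coded_alleles``/``other_alleles`` record which allele each
    dosage counts (for VCF input, the ALT allele); either may hold ``None``
    for panels read from plain TSV matrices without allele annotation.
    NaN entries are designated-missing dosages.
    """

    def __init__(
        self,
        dosages: pd.DataFrame,
        coded_alleles: Mapping[str, str | None] | None = None,
        other_alleles: Mapping[str, str | None] | None = None,
    ):
        dosages = dosages.astype(float)
        vals = dosages.to_numpy()
        bad = (vals < 0) | (vals > 2)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise MrscoreError(
                f"dosage out of [0, 2] for subject {dosages.index[i]!r} "
                f"at variant {dosages.columns[j]!r}: {vals[i, j]}"
            )
        if dosages.columns.duplicated().any():
            raise MrscoreError("duplicate variant ids in dosage panel")
        if dosages.index.duplicated().any():
            raise MrscoreError("duplicate subject ids in dosage panel")
        self.dosages = dosages
        cols = list(dosages.columns)
        self.coded_alleles = {v: (coded_alleles or {}).get(v) for v in cols}
        self.other_alleles = {v: (other_alleles or {}).get(v) for v in cols}

    @property
    def subject_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_subjects(self, subject_ids: Sequence) -> "DosagePanel":
        return DosagePanel(
            self.dosages.loc[list(subject_ids)], self.coded_alleles, self.other_alleles
        )

    def equals(self, other: "DosagePanel", atol: float = 0.0) -> bool:
        if self.variant_ids != other.variant_ids or self.subject_ids != other.subject_ids:
            return False
        a, b = self.dosages.to_numpy(), other.dosages.to_numpy()
        same = np.isclose(a, b, atol=atol, rtol=0.0, equal_nan=True).all()
        return bool(
            same
            and self.coded_alleles == other.coded_alleles
            and self.other_alleles == other.other_alleles
        )


#: canonical cohort columns, in file order
COHORT_COLUMNS = [
    "subject_id",
    "study_id",
    "case",
    "grade_class",
    "stage_class",
    "age_entry",
    "age_exit",
    "died",
    "death_cause",
]


class CohortTable:
    """Per-subject outcomes, subtype labels, follow-up ages and covariates."""

    def __init__(
        self,
        data: pd.DataFrame,
        phenotype_cols: Sequence[str] = (),
        covariate_cols: Sequence[str] = (),
    ):
        df = data.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise MrscoreError(f"cohort table is missing columns: {missing}")
        df["case"] = df["case"].astype(int)
        df["died"] = df["died"].astype(int)
        for col, levels in (("grade_class", GRADE_LEVELS), ("stage_class", STAGE_LEVELS)):
            df[col] = df[col].fillna("unknown")
            bad = ~df[col].isin(levels)
            if bad.any():
                raise MrscoreError(f"invalid {col} value: {df.loc[bad, col].iloc[0]!r}")
        bad = ~df["death_cause"].isin(DEATH_CAUSES)
        if bad.any():
            raise MrscoreError(f"invalid death_cause: {df.loc[bad, 'death_cause'].iloc[0]!r}")
        self._validate(df)
        self.data = df.reset_index(drop=True)
        self.phenotype_cols = list(phenotype_cols)
        self.covariate_cols = list(covariate_cols)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        both = df["age_entry"].notna() & df["age_exit"].notna()
        bad = both & (df["age_exit"] < df["age_entry"])
        if bad.any():
            sid = df.loc[bad, "subject_id"].iloc[0]
            raise MrscoreError(f"subject {sid!r}: age_exit precedes age_entry")
        bad = (df["died"] == 0) & (df["death_cause"] != "alive")
        if bad.any():
            sid = df.loc[bad, "subject_id"].iloc[0]
            raise MrscoreError(f"subject {sid!r}: died=0 but death_cause is not 'alive'")
        controls = df["case"] == 0
        bad = controls & (
            (df["grade_class"] != "unknown") | (df["stage_class"] != "unknown")
        )
        if bad.any():
            sid = df.loc[bad, "subject_id"].iloc[0]
            raise MrscoreError(f"control {sid!r} has a grade/stage label")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        return int((self.data["case"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["case"] == 0).sum())

    @property
    def studies(self) -> list:
        return sorted(self.data["study_id"].unique())

    def cases(self) -> pd.DataFrame:
        return self.data[self.data["case"] == 1]


def complete_followup(cases: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop case rows missing either follow-up age; return (kept, n_dropped).

    Survival analyses run on the age scale require both the entry age
    (diagnosis) and exit age (death or end of follow-up); subjects missing
    either contribute nothing and are excluded, with the count reported.
    """
    ok = cases["age_entry"].notna() & cases["age_exit"].notna()
    return cases[ok], int((~ok).sum())


@dataclass
class EffectEstimate:
    """A log-scale association estimate with its sampling uncertainty.

    ``beta`` is a log odds ratio or log hazard ratio; ``ci_low``/``ci_high``
    are the exponentiated 95% bounds.
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise MrscoreError(f"{self.label or 'estimate'}: se must be positive")
        if not (self.ci_low <= math.exp(self.beta) <= self.ci_high):
            raise MrscoreError(f"{self.label or 'estimate'}: CI does not bracket the estimate")
        if not (0 < self.p <= 1):
            raise MrscoreError(f"{self.label or 'estimate'}: p outside (0, 1]")

    @classmethod
    def from_log(
        cls,
        beta: float,
        se: float,
        n: int,
        label: str = "",
        n_events: int | None = None,
        dof: int | None = None,
    ) -> "EffectEstimate":
        """Build from a log-scale estimate and SE.

        ``dof`` switches the reference distribution from normal to
        Student t (used for cluster-robust fits, where a t with
        G-1 degrees of freedom keeps the test calibrated at small
        cluster counts).
        """
        from scipy.stats import t as t_dist

        if dof is not None and dof >= 1:
            p = float(max(2.0 * t_dist.sf(abs(beta / se), dof), np.nextafter(0, 1)))
            crit = float(t_dist.ppf(0.975, dof))
        else:
            p = float(max(2.0 * norm.sf(abs(beta / se)), np.nextafter(0, 1)))
            crit = Z95
        return cls(
            beta=float(beta),
            se=float(se),
            ci_low=float(np.exp(beta - crit * se)),
            ci_high=float(np.exp(beta + crit * se)),
            p=p,
            n=int(n),
            n_events=n_events,
            label=label,
        )

    @property
    def ratio(self) -> float:
        """The exponentiated estimate (OR or HR)."""
        return float(math.exp(self.beta))

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "estimate": self.ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "n": self.n,
        }
        if self.n_events is not None:
            d["n_events"] = self.n_events
        return d


@dataclass
class AnalysisConfig:
    """Plumbing options shared across pipeline stages."""

    ci_level: float = 0.95
    cluster_correction: bool = True
    standardization_sample: str = "all"  # or "controls"
    drop_ambiguous: bool = False
    missing_dosage: str = "mean"  # or "drop"
    seed: int = 0
    adjust_covariates: list[str] = field(default_factory=list)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.ci_level < 1):
            raise MrscoreError("ci_level must be in (0, 1)")
        self.seed = int(self.seed)
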