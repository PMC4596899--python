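"""Reduced-form association stages of the allele-score analysis.

Every estimate here is the association of the *instrument* (the
standardized genetic risk score) with an outcome — the reduced form whose
sign is a valid test of the causal direction. Case-control models are
cluster-robust logistic regressions with controls always the comparison
group; survival models are cluster-robust Cox fits with delayed entry on
the age scale among cases only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ClusterLogit, CoxResults, LeftTruncatedCox
from .score import ScoreVector
from .types import CohortTable, EffectEstimate, MrscoreError, complete_followup

CASE_SUBSETS = ("all", "localized", "advanced", "low_grade", "high_grade")


def _score_series(score, cohort: CohortTable) -> pd.Series:
    if isinstance(score, ScoreVector):
        s = score.as_series(standardized=True)
    else:
        s = pd.Series(score)
    missing = set(cohort.data["subject_id"]) - set(s.index)
    if missing:
        raise MrscoreError(f"{len(missing)} cohort subjects have no score value")
    return s


def _case_mask(df: pd.DataFrame, subset: str) -> pd.Series:
    if subset == "all":
        return df["case"] == 1
    if subset == "localized":
        return (df["case"] == 1) & (df["stage_class"] == "localized")
    if subset == "advanced":
        return (df["case"] == 1) & (df["stage_class"] == "advanced")
    if subset == "low_grade":
        return (df["case"] == 1) & (df["grade_class"] == "low")
    if subset == "high_grade":
        return (df["case"] == 1) & (df["grade_class"] == "high")
    raise MrscoreError(f"unknown case subset {subset!r}; one of {CASE_SUBSETS}")


def reduced_form_or(
    cohort: CohortTable,
    score,
    case_subset: str = "all",
    adjust: pd.DataFrame | None = None,
    cluster: bool = True,
) -> EffectEstimate:
    """Odds ratio of case status per SD of score, controls as comparison.

    ``adjust`` may carry extra per-subject columns (e.g. genotype PCs),
    indexed by subject id.
    """
    s = _score_series(score, cohort)
    df = cohort.data
    mask = _case_mask(df, case_subset) | (df["case"] == 0)
    sub = df[mask]
    if (sub["case"] == 1).sum() == 0:
        raise MrscoreError(f"case subset {case_subset!r} is empty")
    y = sub["case"].to_numpy()
    X = s.loc[sub["subject_id"]].to_numpy()[:, None]
    names = ["score"]
    if adjust is not None:
        A = adjust.loc[sub["subject_id"]]
        X = np.column_stack([X, A.to_numpy()])
        names += list(A.columns)
    groups = sub["study_id"].to_numpy() if cluster else None
    res = ClusterLogit(y, X, groups=groups, exog_names=names).fit()
    return res.effect_estimate(
        "score",
        label=f"reduced_form:{case_subset}"
        + (":adjusted" if adjust is not None else "")
        + (":clustered" if cluster else ""),
    )


def case_only_heterogeneity(
    cohort: CohortTable, score, axis: str = "grade", cluster: bool = True
) -> EffectEstimate:
    """Subtype-difference test: subtype regressed on score among cases only.

    The returned p is the heterogeneity p for advanced-vs-localized
    (axis="stage") or high-vs-low grade (axis="grade"); beta is the
    difference in per-SD log-OR between the two subtypes.
    """
    df = cohort.cases()
    if axis == "grade":
        sub = df[df["grade_class"].isin(("low", "high"))]
        y = (sub["grade_class"] == "high").astype(int).to_numpy()
        levels = ("low", "high")
    elif axis == "stage":
        sub = df[df["stage_class"].isin(("localized", "advanced"))]
        y = (sub["stage_class"] == "advanced").astype(int).to_numpy()
        levels = ("localized", "advanced")
    else:
        raise MrscoreError(f"unknown heterogeneity axis {axis!r}")
    if len(np.unique(y)) < 2:
        raise MrscoreError(f"both {axis} levels must be present among cases")
    s = _score_series(score, cohort).loc[sub["subject_id"]].to_numpy()
    if np.std(s) == 0:
        raise MrscoreError("score is constant among cases")
    groups = sub["study_id"].to_numpy() if cluster else None
    res = ClusterLogit(y, s[:, None], groups=groups, exog_names=["score"]).fit()
    return res.effect_estimate("score", label=f"case_only_heterogeneity:{axis}:"
                               + "_vs_".join(levels))


def quintile_contrast(
    cohort: CohortTable,
    quintiles: np.ndarray | pd.Series,
    case_subset: str = "all",
    cluster: bool = True,
) -> EffectEstimate:
    """OR of case status, top vs bottom score quintile, middle groups excluded."""
    if isinstance(quintiles, pd.Series):
        q = quintiles
    else:
        q = pd.Series(np.asarray(quintiles), index=cohort.data["subject_id"])
    df = cohort.data
    mask = _case_mask(df, case_subset) | (df["case"] == 0)
    sub = df[mask]
    qv = q.loc[sub["subject_id"]].to_numpy()
    extreme = (qv == 1) | (qv == 5)
    sub = sub[extreme]
    qv = qv[extreme]
    for grp in (1, 5):
        sel = qv == grp
        if (sub.loc[sel, "case"] == 1).sum() == 0 or (sub.loc[sel, "case"] == 0).sum() == 0:
            raise MrscoreError(
                f"quintile group {grp} lacks cases or controls; contrast undefined"
            )
    y = sub["case"].to_numpy()
    x = (qv == 5).astype(float)[:, None]
    groups = sub["study_id"].to_numpy() if cluster else None
    res = ClusterLogit(y, x, groups=groups, exog_names=["top_vs_bottom"]).fit()
    return res.effect_estimate(
        "top_vs_bottom", label=f"quintile_contrast:{case_subset}"
    )


@dataclass
class MetaResult:
    """Fixed-effect inverse-variance pooling of per-study estimates."""

    per_study: list[EffectEstimate]
    pooled_beta: float
    pooled_se: float
    q_stat: float
    i2: float
    dropped_studies: list = field(default_factory=list)

    @property
    def pooled(self) -> EffectEstimate:
        return EffectEstimate.from_log(
            self.pooled_beta, self.pooled_se,
            n=sum(e.n for e in self.per_study), label="meta:pooled",
        )


def pool_fixed_effect(betas, ses, labels=None, ns=None) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q and I².

    I² = max(0, (Q - (G-1)) / Q) * 100, the percentage of between-study
    variability beyond what sampling error explains.
    """
    b = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    if np.any(se <= 0):
        raise MrscoreError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (b - pooled) ** 2))
    g = len(b)
    i2 = 0.0 if q <= 0 else max(0.0, (q - (g - 1)) / q) * 100.0
    per = [
        EffectEstimate.from_log(
            b[i], se[i],
            n=(ns[i] if ns is not None else 0) or 1,
            label=(labels[i] if labels is not None else f"study{i+1}"),
        )
        for i in range(g)
    ]
    return MetaResult(per, pooled, pooled_se, q, i2)


def per_study_meta(cohort: CohortTable, score) -> MetaResult:
    """Per-study (unclustered) logistic fits pooled under a fixed-effect model."""
    s = _score_series(score, cohort)
    betas, ses, labels, ns = [], [], [], []
    dropped = []
    for study in cohort.studies:
        sub = cohort.data[cohort.data["study_id"] == study]
        if sub["case"].nunique() < 2:
            dropped.append(study)
            continue
        x = s.loc[sub["subject_id"]].to_numpy()[:, None]
        res = ClusterLogit(sub["case"].to_numpy(), x, groups=None,
                           exog_names=["score"]).fit()
        j = res.exog_names.index("score")
        betas.append(res.params[j])
        ses.append(res.bse[j])
        labels.append(str(study))
        ns.append(len(sub))
    if dropped:
        warnings.warn(
            f"studies without both outcome levels dropped from meta-analysis: {dropped}",
            stacklevel=2,
        )
    if len(betas) < 2:
        raise MrscoreError("need at least 2 usable studies for meta-analysis")
    out = pool_fixed_effect(betas, ses, labels, ns)
    out.dropped_studies = dropped
    return out


@dataclass
class SurvivalSpec:
    """Configuration of a survival stage.

    ``event``: "all-cause" counts any death; "disease-specific" counts
    disease deaths and censors other-cause deaths. Entry is the age at
    diagnosis, exit the age at death or final follow-up.
    """

    event: str = "all-cause"
    case_subset: str = "all"
    adjust: list[str] = field(default_factory=list)
    cluster: str | None = "study_id"

    def __post_init__(self):
        if self.event not in ("all-cause", "disease-specific"):
            raise MrscoreError(f"unknown event definition {self.event!r}")


def fit_cox_cluster(
    spec: SurvivalSpec,
    cohort: CohortTable,
    score,
    adjust: pd.DataFrame | None = None,
) -> CoxResults:
    """Cluster-robust left-truncated Cox fit of mortality on the score.

    Cases only; subjects missing either follow-up age are excluded and
    counted in ``results.n_excluded``.
    """
    s = _score_series(score, cohort)
    df = cohort.data
    sub = df[_case_mask(df, spec.case_subset)]
    if len(sub) == 0:
        raise MrscoreError(f"case subset {spec.case_subset!r} is empty")
    sub, n_excluded = complete_followup(sub)
    if len(sub) == 0:
        raise MrscoreError("no cases with complete follow-up ages")
    if spec.event == "all-cause":
        event = (sub["died"] == 1).astype(int)
    else:
        event = ((sub["died"] == 1) & (sub["death_cause"] == "disease")).astype(int)
    X = s.loc[sub["subject_id"]].to_numpy()[:, None]
    names = ["score"]
    if adjust is not None:
        A = adjust.loc[sub["subject_id"]]
        X = np.column_stack([X, A.to_numpy()])
        names += list(A.columns)
    for cov in spec.adjust:
        X = np.column_stack([X, sub[cov].to_numpy()])
        names.append(cov)
    groups = sub[spec.cluster].to_numpy() if spec.cluster else None
    model = LeftTruncatedCox(
        sub["age_entry"].to_numpy(), sub["age_exit"].to_numpy(),
        event.to_numpy(), X, groups=groups, exog_names=names,
    )
    res = model.fit()
    res.n_excluded = n_excluded
    return res


def cox_effect(
    spec: SurvivalSpec, cohort: CohortTable, score, adjust: pd.DataFrame | None = None
) -> EffectEstimate:
    """Hazard ratio per SD of score under ``spec`` as an EffectEstimate."""
    res = fit_cox_cluster(spec, cohort, score, adjust=adjust)
    return res.effect_estimate(
        "score",
        label=f"cox:{spec.event}:{spec.case_subset}"
        + (":adjusted" if (adjust is not None or spec.adjust) else ""),
    )
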