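"""Instrument-strength diagnostics, MR power, genotype PCs, confounder scan.

The first stage regresses the (standardized) phenotype on the
(standardized) score; its R² and F statistic measure instrument strength,
and the closed-form power calculation translates R² into the detectable
odds ratio for a binary outcome at a given case/control split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import DosagePanel, EffectEstimate, MrscoreError, Z95


@dataclass
class InstrumentDiagnostics:
    n: int
    beta: float           # phenotype SD per score SD
    ci_low: float
    ci_high: float
    r2: float
    f_stat: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "r2": self.r2,
            "f_stat": self.f_stat,
        }


@dataclass
class PowerInput:
    n_cases: int
    n_controls: int
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise MrscoreError("case/control counts must be positive")
        if self.or_alt <= 0:
            raise MrscoreError("or_alt must be positive")
        if not (0 < self.alpha < 1):
            raise MrscoreError("alpha must be in (0, 1)")
        if not (0 <= self.r2 < 1):
            raise MrscoreError("r2 must be in [0, 1)")


def first_stage(score: np.ndarray, phenotype: np.ndarray) -> InstrumentDiagnostics:
    """Simple linear regression of phenotype on score.

    r² is the squared correlation and F = (n-2) r² / (1-r²); with a perfect
    fit F is reported as +inf with a warning.
    """
    x = np.asarray(score, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise MrscoreError("need at least 3 complete pairs")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise MrscoreError("constant score: first stage undefined")
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    beta = sxy / sxx
    r2 = 0.0 if syy == 0 else float(sxy**2 / (sxx * syy))
    if r2 >= 1.0 - 1e-15:
        warnings.warn("perfect first-stage fit; F reported as +inf", stacklevel=2)
        f = float("inf")
        se = 0.0
        return InstrumentDiagnostics(n, float(beta), float(beta), float(beta), 1.0, f)
    f = (n - 2) * r2 / (1.0 - r2)
    sigma2 = (syy - beta * sxy) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    return InstrumentDiagnostics(
        n, float(beta), float(beta - Z95 * se), float(beta + Z95 * se), r2, float(f)
    )


def mr_power_binary(inp: PowerInput) -> float:
    """Closed-form power of the reduced-form test for a binary outcome.

    With N subjects of whom a fraction K are cases and an instrument
    explaining R² of the exposure variance, the per-exposure-SD log odds
    ratio b under the alternative is detected with power

        Phi( sqrt(N K (1-K) R²) |b| - z_{1-alpha/2} ).
    """
    n = inp.n_cases + inp.n_controls
    k = inp.n_cases / n
    z = norm.ppf(1 - inp.alpha / 2)
    if inp.r2 == 0:
        warnings.warn("r2 = 0: instrument carries no information", stacklevel=2)
        return float(norm.cdf(-z))
    ncp = np.sqrt(n * k * (1 - k) * inp.r2) * abs(np.log(inp.or_alt))
    return float(norm.cdf(ncp - z))


def genotype_pcs(panel: DosagePanel, k: int = 8) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of the column-centered dosage matrix.

    Returns per-subject coordinates (columns PC1..PCk) and the explained
    variance fractions. Sign convention: the largest-magnitude variant
    loading on each axis is positive.
    """
    D = panel.dosages.to_numpy(dtype=float, copy=True)
    col_means = np.nanmean(D, axis=0)
    nan_r, nan_c = np.where(np.isnan(D))
    D[nan_r, nan_c] = col_means[nan_c]
    D = D - D.mean(axis=0)
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise MrscoreError(f"k={k} exceeds the rank ({rank}) of the centered dosage matrix")
    signs = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    coords = U[:, :k] * s[:k] * signs[:k]
    explained = s**2 / np.sum(s**2)
    out = pd.DataFrame(
        coords, index=panel.dosages.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return out, explained[:k]


def covariate_scan(
    score: pd.Series,
    cohort,
    covariates: list[str],
    cluster: bool = True,
) -> pd.DataFrame:
    """Association of the standardized score with each candidate confounder.

    Binary covariates get a logistic odds ratio per SD of score; continuous
    covariates a linear mean difference per SD, both with robust standard
    errors (clustered by study when more than one study is present).
    Single-level covariates are skipped with a warning.
    """
    from .models import ClusterLogit, ClusterOLS

    df = cohort.data.set_index("subject_id")
    rows = []
    for name in covariates:
        sub = pd.DataFrame({"y": df[name], "score": score, "study": df["study_id"]}).dropna()
        vals = sub["y"].unique()
        groups = sub["study"] if (cluster and sub["study"].nunique() > 1) else None
        if len(vals) < 2:
            warnings.warn(f"covariate {name!r} has a single level; skipped", stacklevel=2)
            continue
        is_binary = len(vals) == 2 and set(np.unique(vals)).issubset({0, 1, 0.0, 1.0})
        x = sub[["score"]].to_numpy()
        if is_binary:
            res = ClusterLogit(sub["y"].to_numpy(), x, groups=groups,
                               exog_names=["score"]).fit()
            est = res.effect_estimate("score", label=f"covariate_scan:{name}:odds_ratio")
            row = {
                "covariate": name,
                "type": "odds_ratio",
                "n": est.n,
                "estimate": est.ratio,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
            }
        else:
            res = ClusterOLS(sub["y"].to_numpy(), x, groups=groups,
                             exog_names=["score"]).fit()
            j = res.exog_names.index("score")
            lo, hi = res.conf_int()[j]
            row = {
                "covariate": name,
                "type": "mean_difference",
                "n": res.nobs,
                "estimate": res.params[j],
                "ci_low": lo,
                "ci_high": hi,
                "p": res.pvalues[j],
            }
        rows.append(row)
    return pd.DataFrame(rows)
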