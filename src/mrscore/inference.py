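"""Between-estimate heterogeneity, Wald rescaling, and instrument splits.

The reduced-form estimates are on the per-score-SD scale. To express them
per unit of the phenotype, the log-effect is divided by the first-stage
coefficient: for jointly standardized score and phenotype that coefficient
equals the correlation, i.e. sqrt(R²), optionally times the phenotype SD
in target units (e.g. 3.5 kg/m² for per-kg/m² BMI effects). The
Altman-Bland z-test compares two independent estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .harmonize import harmonize
from .score import build_score, split_weights, standardize
from .types import EffectEstimate, MrscoreError, Z95


@dataclass
class RescaleSpec:
    """Constants of the Wald rescaling (treated as fixed, no uncertainty)."""

    r2: float
    unit_sd: float = 1.0

    def __post_init__(self):
        if not (0 < self.r2 <= 1):
            raise MrscoreError("r2 must be in (0, 1]")
        if self.unit_sd <= 0:
            raise MrscoreError("unit_sd must be positive")


@dataclass
class HeterogeneityResult:
    z: float
    p: float
    diff: float
    se_diff: float


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error of a log estimate recovered from its printed CI.

    se = (ln hi - ln lo) / (2 z); for the 95% level z = 1.959964 exactly,
    so printed tables round-trip bit-reproducibly.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise MrscoreError("CI bounds must be positive")
    if ci_high < ci_low:
        raise MrscoreError("ci_high must be >= ci_low")
    z = Z95 if level == 0.95 else float(norm.ppf((1 + level) / 2))
    return float((np.log(ci_high) - np.log(ci_low)) / (2 * z))


def altman_bland(beta1: float, se1: float, beta2: float, se2: float) -> HeterogeneityResult:
    """z-test for the difference of two independent log-scale estimates.

    z = (beta1 - beta2) / sqrt(se1² + se2²), two-sided normal p.
    """
    if se1 <= 0 or se2 <= 0:
        raise MrscoreError("standard errors must be positive")
    se_diff = float(np.sqrt(se1**2 + se2**2))
    diff = float(beta1 - beta2)
    z = diff / se_diff
    p = float(min(2.0 * norm.sf(abs(z)), 1.0))
    return HeterogeneityResult(z=z, p=p, diff=diff, se_diff=se_diff)


def altman_bland_estimates(e1: EffectEstimate, e2: EffectEstimate) -> HeterogeneityResult:
    return altman_bland(e1.beta, e1.se, e2.beta, e2.se)


def wald_rescale(estimate: EffectEstimate, spec: RescaleSpec) -> EffectEstimate:
    """Rescale a per-score-SD estimate to the phenotype scale.

    beta_out = beta_in / (sqrt(r2) * unit_sd); the CI bounds transform by
    the same divisor on the log scale. No uncertainty in r2 or unit_sd is
    propagated (point-value convention).
    """
    denom = float(np.sqrt(spec.r2) * spec.unit_sd)
    beta = estimate.beta / denom
    se = estimate.se / denom
    return EffectEstimate(
        beta=beta,
        se=se,
        ci_low=float(np.exp(np.log(estimate.ci_low) / denom)),
        ci_high=float(np.exp(np.log(estimate.ci_high) / denom)),
        p=estimate.p,
        n=estimate.n,
        n_events=estimate.n_events,
        label=(estimate.label + f"|rescaled(r2={spec.r2:g},unit_sd={spec.unit_sd:g})"),
    )


def split_instrument_analysis(
    cohort,
    panel,
    weights,
    mode: str = "random_halves",
    outcome_stage=None,
    seed: int = 0,
    named_variant: str | None = None,
    phenotype: str | None = None,
) -> tuple[EffectEstimate, EffectEstimate, HeterogeneityResult]:
    """Pleiotropy probe: the same outcome stage run on two disjoint sub-scores.

    Each half is harmonized, scored and standardized independently, the
    designated outcome stage (default: the all-cancers reduced form) is run
    on each, and the two estimates are compared with the Altman-Bland test.
    When ``phenotype`` names a cohort phenotype column, each half's estimate
    is first Wald-rescaled by its own first-stage sqrt(R²) so the comparison
    is on the shared per-phenotype-SD scale (the halves explain different
    fractions of the phenotype); otherwise the per-score-SD estimates are
    compared directly.
    """
    from .analysis import reduced_form_or
    from .instruments import first_stage

    if outcome_stage is None:
        outcome_stage = lambda c, s: reduced_form_or(c, s, case_subset="all")

    w1, w2 = split_weights(weights, mode=mode, seed=seed, named_variant=named_variant)
    estimates = []
    for w in (w1, w2):
        p = harmonize(panel, w)
        sc = standardize(build_score(p, w))
        est = outcome_stage(cohort, sc)
        if phenotype is not None:
            ph = cohort.data.set_index("subject_id")[phenotype]
            z = (ph - ph.mean()) / ph.std(ddof=1)
            diag = first_stage(
                sc.as_series().loc[z.index].to_numpy(), z.to_numpy()
            )
            est = wald_rescale(est, RescaleSpec(r2=max(diag.r2, 1e-12)))
        estimates.append(est)
    het = altman_bland_estimates(estimates[0], estimates[1])
    return estimates[0], estimates[1], het
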