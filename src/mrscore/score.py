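"""Weighted allele scores: construction, standardization, quintiles, splits.

The genetic risk score of subject i is S_i = sum_j w_j d_ij over the
instrument variants (or the unweighted allele count when mode is
"unweighted"). Scores are standardized to mean zero, SD one over a
designated standardization sample and analysed per SD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .types import DosagePanel, MrscoreError, WeightTable


@dataclass
class ScoreVector:
    subject_ids: pd.Index
    raw: np.ndarray
    standardized: np.ndarray | None = None
    mode: str = "weighted"
    n_variants: int = 0

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.standardized is not None:
            self.standardized = np.asarray(self.standardized, dtype=float)

    def __len__(self) -> int:
        return len(self.raw)

    def as_series(self, standardized: bool = True) -> pd.Series:
        vals = self.standardized if standardized else self.raw
        if vals is None:
            raise MrscoreError("score has not been standardized")
        return pd.Series(vals, index=self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids, "raw": self.raw})
        if self.standardized is not None:
            df["standardized"] = self.standardized
        return df


def build_score(panel: DosagePanel, weights: WeightTable, mode: str = "weighted") -> ScoreVector:
    """S_i = sum_j w_j d_ij (weighted) or sum_j d_ij (unweighted).

    The panel must already be harmonized to the weight table (same variants,
    coded on effect alleles).
    """
    if len(weights) == 0:
        raise MrscoreError("empty weight set")
    ids = [v.variant_id for v in weights if v.variant_id in set(panel.variant_ids)]
    if not ids:
        raise MrscoreError("no weight variants present in the panel; harmonize first")
    D = panel.dosages[ids].to_numpy()
    if np.isnan(D).any():
        raise MrscoreError("panel has missing dosages; harmonize with an imputation policy")
    if mode == "weighted":
        w = np.array([weights[i].weight for i in ids])
        raw = D @ w
    elif mode == "unweighted":
        raw = D.sum(axis=1)
    else:
        raise MrscoreError(f"unknown scoring mode {mode!r}")
    return ScoreVector(panel.dosages.index, raw, mode=mode, n_variants=len(ids))


def standardize(score: ScoreVector, sample: Sequence | None = None) -> ScoreVector:
    """Center/scale to SD units using the designated standardization sample.

    Subjects outside the sample are transformed with the same constants.
    SD uses the n-1 divisor.
    """
    if sample is None:
        mask = np.ones(len(score), dtype=bool)
    else:
        mask = np.isin(np.asarray(score.subject_ids), np.asarray(list(sample)))
    vals = score.raw[mask]
    if len(vals) < 2:
        raise MrscoreError("standardization sample too small")
    mu, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
    if sd == 0:
        raise MrscoreError("standardization sample has zero SD")
    return replace(score, standardized=(score.raw - mu) / sd)


def quintile_groups(score: ScoreVector, sample: Sequence | None = None) -> np.ndarray:
    """Assign groups 1..5 by the 20/40/60/80th percentiles of the sample.

    Ties at a cut point go to the lower group (a value equal to a cut is
    not above it), which makes the assignment deterministic and
    order-independent.
    """
    vals = score.raw
    if sample is not None:
        mask = pd.Index(score.subject_ids).isin(pd.Index(sample)).astype(bool)
        ref = vals[np.asarray(mask)]
    else:
        ref = vals
    if len(np.unique(ref)) < 5:
        raise MrscoreError("need at least 5 distinct score values for quintiles")
    cuts = np.quantile(ref, [0.2, 0.4, 0.6, 0.8])
    return 1 + (vals[:, None] > cuts[None, :]).sum(axis=1)


def split_weights(
    weights: WeightTable,
    mode: str = "random_halves",
    seed: int = 0,
    named_variant: str | None = None,
) -> tuple[WeightTable, WeightTable]:
    """Partition the instrument into two disjoint, exhaustive sub-instruments.

    ``random_halves`` permutes the variants with the given seed and cuts at
    floor(m/2); ``named_variant_vs_rest`` isolates one named variant (the
    FTO-style largest-effect SNP) from the remainder.
    """
    m = len(weights)
    if m < 2:
        raise MrscoreError("need at least 2 variants to split")
    ids = weights.variant_ids
    if mode == "random_halves":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(m)
        first = sorted(perm[: m // 2])
        second = sorted(perm[m // 2 :])
        return weights.subset([ids[i] for i in first]), weights.subset(
            [ids[i] for i in second]
        )
    if mode == "named_variant_vs_rest":
        if named_variant is None or named_variant not in weights:
            raise MrscoreError(f"named variant {named_variant!r} not in the weight table")
        rest = [i for i in ids if i != named_variant]
        return weights.subset([named_variant]), weights.subset(rest)
    raise MrscoreError(f"unknown split mode {mode!r}")


def write_scores(score: ScoreVector, quintiles: np.ndarray | None, path) -> None:
    df = score.to_frame()
    if quintiles is not None:
        df["quintile"] = quintiles
    df.to_csv(path, sep="\t", index=False, na_rep=".", encoding="utf-8")
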