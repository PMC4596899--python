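"""Align dosage panels to the effect alleles of a weight table.

Dosages count copies of the panel's coded allele. Scoring needs them to
count copies of the weight table's *effect* allele, so variants coded on
the other allele are flipped (d -> 2 - d). Strand-ambiguous variants
(A/T, C/G pairs) cannot be checked against strand flips without reference
frequencies, so they are harmonized by allele label and reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import DosagePanel, MrscoreError, WeightTable

#: fraction of weight variants allowed to be absent before a hard error
MAX_MISSING_FRACTION = 0.20


class HarmonizationWarning(UserWarning):
    pass


def harmonize(
    panel: DosagePanel,
    weights: WeightTable,
    drop_ambiguous: bool = False,
    missing_dosage: str = "mean",
) -> DosagePanel:
    """Return a panel restricted to the weight variants, coded on effect alleles.

    Variants absent from the panel are dropped with a warning (hard error
    when more than 20% are absent). Missing per-subject dosages are imputed
    with the variant's mean dosage (``missing_dosage="mean"``) or the
    subjects carrying them dropped (``"drop"``).
    """
    absent = [v.variant_id for v in weights if v.variant_id not in set(panel.variant_ids)]
    if len(absent) / len(weights) > MAX_MISSING_FRACTION:
        raise MrscoreError(
            f"{len(absent)}/{len(weights)} weight variants absent from the panel "
            f"(> {MAX_MISSING_FRACTION:.0%}): {absent[:10]}..."
            if len(absent) > 10
            else f"{len(absent)}/{len(weights)} weight variants absent from the panel "
            f"(> {MAX_MISSING_FRACTION:.0%}): {absent}"
        )
    if absent:
        warnings.warn(
            f"{len(absent)} weight variant(s) absent from the panel, dropped: {absent}",
            HarmonizationWarning,
            stacklevel=2,
        )
    kept = [v for v in weights if v.variant_id not in absent]

    ambiguous = [v.variant_id for v in kept if v.is_strand_ambiguous]
    if ambiguous:
        if drop_ambiguous:
            warnings.warn(
                f"dropping {len(ambiguous)} strand-ambiguous variant(s): {ambiguous}",
                HarmonizationWarning,
                stacklevel=2,
            )
            kept = [v for v in kept if not v.is_strand_ambiguous]
        else:
            warnings.warn(
                "strand-ambiguous variant(s) harmonized by allele label only: "
                f"{ambiguous}",
                HarmonizationWarning,
                stacklevel=2,
            )
    if not kept:
        raise MrscoreError("no variants left to harmonize")

    cols = {}
    coded, other = {}, {}
    unannotated = []
    for v in kept:
        d = panel.dosages[v.variant_id].to_numpy(copy=True)
        c = panel.coded_alleles[v.variant_id]
        o = panel.other_alleles[v.variant_id]
        if c is None:
            unannotated.append(v.variant_id)
        elif c == v.effect_allele:
            pass
        elif c == v.other_allele:
            d = 2.0 - d
        else:
            raise MrscoreError(
                f"variant {v.variant_id}: panel coded allele {c!r} matches neither "
                f"effect ({v.effect_allele}) nor other ({v.other_allele}) allele"
            )
        cols[v.variant_id] = d
        coded[v.variant_id] = v.effect_allele
        other[v.variant_id] = v.other_allele
    if unannotated:
        warnings.warn(
            "panel carries no allele annotation for "
            f"{len(unannotated)} variant(s); dosages assumed to count the effect "
            f"allele: {unannotated}",
            HarmonizationWarning,
            stacklevel=2,
        )

    df = pd.DataFrame(cols, index=panel.dosages.index)
    if df.isna().to_numpy().any():
        if missing_dosage == "mean":
            df = df.fillna(df.mean())
        elif missing_dosage == "drop":
            df = df.dropna()
        else:
            raise MrscoreError(f"unknown missing_dosage policy {missing_dosage!r}")
    return DosagePanel(df, coded, other)


def flip_panel(panel: DosagePanel) -> DosagePanel:
    """Swap every variant's allele orientation (d -> 2 - d, alleles exchanged).

    Utility for tests of flip invariance; requires full allele annotation.
    """
    coded = {v: panel.other_alleles[v] for v in panel.variant_ids}
    other = {v: panel.coded_alleles[v] for v in panel.variant_ids}
    if any(a is None for a in coded.values()):
        raise MrscoreError("cannot flip a panel without allele annotation")
    return DosagePanel(2.0 - panel.dosages, coded, other)
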