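"""Readers and writers for weight tables, dosage panels and cohort tables.

All text outputs are UTF-8, tab-delimited, with ``.`` for missing values.
Dosage panels can be read either from a VCF carrying a per-genotype ``DS``
(dosage) FORMAT field, or from a plain TSV matrix whose header holds the
variant ids — optionally annotated as ``variant:coded:other`` so allele
orientation survives the round trip.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    COHORT_COLUMNS,
    CohortTable,
    DosagePanel,
    MrscoreError,
    VariantWeight,
    WeightTable,
)

MISSING = "."


# ---------------------------------------------------------------- weights

def read_weights(path) -> WeightTable:
    """Read a tab-separated weight table.

    Expected header: ``variant_id  effect_allele  other_allele  weight``
    (an optional ``phenotype_tag`` column is honoured).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["variant_id", "effect_allele", "other_allele", "weight"]
        if [c for c in required if c not in header]:
            raise MrscoreError(f"{path}: weight table header must contain {required}")
        idx = {c: header.index(c) for c in header}
        has_tag = "phenotype_tag" in idx
        variants = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                w = float(parts[idx["weight"]])
            except (ValueError, IndexError) as exc:
                raise MrscoreError(f"{path}:{lineno}: unparseable weight") from exc
            if not math.isfinite(w):
                raise MrscoreError(f"{path}:{lineno}: weight is not finite")
            variants.append(
                VariantWeight(
                    variant_id=parts[idx["variant_id"]],
                    effect_allele=parts[idx["effect_allele"]],
                    other_allele=parts[idx["other_allele"]],
                    weight=w,
                    phenotype_tag=parts[idx["phenotype_tag"]] if has_tag else "custom",
                )
            )
    return WeightTable(variants)


def write_weights(table: WeightTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------- dosages

def _split_header_token(tok: str) -> tuple[str, str | None, str | None]:
    parts = tok.split(":")
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    return tok, None, None


def read_dosages(path, format: str = "tsv") -> DosagePanel:
    """Read a dosage panel from ``tsv`` or ``vcf``.

    TSV: first column is the subject id, remaining columns one variant each
    (header token either a bare id or ``id:coded:other``); ``.`` marks a
    missing dosage. VCF: dosages come from the per-genotype ``DS`` field,
    the coded allele is the ALT allele; multi-allelic records are rejected.
    """
    if format == "tsv":
        return _read_dosages_tsv(path)
    if format == "vcf":
        return _read_dosages_vcf(path)
    raise MrscoreError(f"unknown dosage format {format!r}")


def _read_dosages_tsv(path) -> DosagePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], dtype=str)
    coded, other = {}, {}
    cols = []
    for tok in df.columns:
        vid, c, o = _split_header_token(tok)
        cols.append(vid)
        coded[vid], other[vid] = c, o
    df.columns = cols
    return DosagePanel(df.astype(float), coded, other)


def _read_dosages_vcf(path) -> DosagePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    coded, other = {}, {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise MrscoreError(f"multi-allelic record at {rec.ID or rec.POS}")
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            raise MrscoreError(f"record {rec.ID or rec.POS} has no DS dosage field")
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        columns[vid] = np.asarray(ds, dtype=float).reshape(-1)
        coded[vid] = rec.ALT[0]
        other[vid] = rec.REF
    vcf.close()
    if not columns:
        raise MrscoreError(f"{path}: no usable records")
    df = pd.DataFrame(columns, index=subjects)
    return DosagePanel(df, coded, other)


def write_dosages(panel: DosagePanel, path) -> None:
    """Write a panel as a TSV matrix, preserving allele annotation."""
    header_tokens = []
    for vid in panel.variant_ids:
        c, o = panel.coded_alleles[vid], panel.other_alleles[vid]
        header_tokens.append(f"{vid}:{c}:{o}" if c is not None and o is not None else vid)
    out = panel.dosages.copy()
    out.columns = header_tokens
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep=MISSING, encoding="utf-8")


# ---------------------------------------------------------------- cohort

def read_cohort(path, column_map: dict[str, str] | None = None) -> CohortTable:
    """Read a delimited cohort table (tab or comma separated).

    ``column_map`` renames file columns onto the canonical names. Grade and
    stage values not recognised are mapped to ``unknown`` for cases; any
    non-canonical column is carried as a covariate/phenotype column.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=[MISSING])
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("grade_class", "stage_class"):
        if col in df.columns:
            df[col] = df[col].where(df[col].isin(("low", "high", "localized", "advanced")))
    if "death_cause" in df.columns:
        df["death_cause"] = df["death_cause"].fillna("alive")
    # grade/stage on a control row is a data error, not an unknown
    if "case" in df.columns:
        ctrl = df["case"] == 0
        raw = pd.read_csv(path, sep=sep, dtype=str, na_values=[MISSING])
        if column_map:
            raw = raw.rename(columns=column_map)
        for col in ("grade_class", "stage_class"):
            if col in raw.columns:
                bad = ctrl & raw[col].notna()
                if bad.any():
                    sid = df.loc[bad, "subject_id"].iloc[0]
                    raise MrscoreError(f"control {sid!r} has a {col} label")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    phenos = [c for c in extra if c in ("height", "bmi")]
    covars = [c for c in extra if c not in phenos]
    return CohortTable(df, phenotype_cols=phenos, covariate_cols=covars)


def write_cohort(cohort: CohortTable, path) -> None:
    cols = COHORT_COLUMNS + cohort.phenotype_cols + cohort.covariate_cols
    out = cohort.data[cols].copy()
    for col in ("grade_class", "stage_class"):
        out[col] = out[col].where(out[col] != "unknown")
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING, encoding="utf-8")


def write_vcf(panel: DosagePanel, path, chrom: str = "1") -> None:
    """Write a panel as a minimal single-chromosome VCF with DS dosages.

    Intended for fixtures and round-trip checks; positions are synthetic
    (sequential), REF/ALT come from the panel's allele annotation.
    """
    subjects = panel.subject_ids
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in subjects)
            + "\n"
        )
        for pos, vid in enumerate(panel.variant_ids, start=1):
            ref = panel.other_alleles[vid] or "A"
            alt = panel.coded_alleles[vid] or "G"
            vals = panel.dosages[vid].to_numpy()
            cells = "\t".join("." if np.isnan(v) else f"{v:g}" for v in vals)
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tDS\t{cells}\n")
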