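"""Configured, seeded, end-to-end analysis pipeline.

Executes the full sequence — simulate/read, harmonize, score and
standardize, instrument diagnostics and power, reduced-form odds ratios
by case subset, quintile contrast, per-study meta-analysis, case-only
subtype heterogeneity, cluster-robust survival models, Altman-Bland
subtype comparisons, instrument splits, and Wald rescaling — and writes
a structured report (TSV + JSON) plus a run manifest with input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .analysis import (
    SurvivalSpec,
    case_only_heterogeneity,
    cox_effect,
    per_study_meta,
    quintile_contrast,
    reduced_form_or,
)
from .harmonize import harmonize
from .inference import (
    RescaleSpec,
    altman_bland_estimates,
    split_instrument_analysis,
    wald_rescale,
)
from .instruments import PowerInput, covariate_scan, first_stage, genotype_pcs, mr_power_binary
from .score import build_score, quintile_groups, standardize
from .simulate import SimulationSpec, simulate_consortium
from .types import MrscoreError

log = logging.getLogger("mrscore")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    completed: bool = False

    def record(self, stage: str, seconds: float) -> None:
        self.stages.append({"stage": stage, "seconds": round(seconds, 3)})

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "stages": self.stages,
            "outputs": self.outputs,
            "completed": self.completed,
        }


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulate": SimulationSpec(seed=seed).to_dict(),
        "adjust_pcs": 8,
        "standardization_sample": "all",
        "power": {"alpha": 0.05, "or_alt": {"height": 1.12, "bmi": 1.25}},
        "rescale": {
            "height": {"r2": 0.10, "unit_sd": 1.0},
            "bmi": {"r2": 0.0145, "unit_sd": 3.5},
        },
    }


class _Stage:
    """Context manager timing one pipeline stage and naming it on failure."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        log.info("stage %s", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.record(self.name, time.perf_counter() - self.t0)
        if exc is not None:
            log.error("stage %s failed: %s", self.name, exc)
            raise MrscoreError(f"pipeline aborted in stage {self.name!r}: {exc}") from exc


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute every stage; on failure the partial manifest is still written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)
    try:
        return _run(config, out, seed, manifest)
    except Exception:
        (out / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2, sort_keys=True, default=_coerce),
            encoding="utf-8",
        )
        raise


def _run(config: dict, out: Path, seed: int, manifest: RunManifest) -> RunManifest:
    rows: list[dict] = []
    extras: dict = {}

    with _Stage(manifest, "inputs"):
        if "inputs" in config:
            paths = config["inputs"]
            weights = mio.read_weights(paths["weights"])
            panel = mio.read_dosages(paths["dosages"], paths.get("dosages_format", "tsv"))
            cohort = mio.read_cohort(paths["cohort"])
            for key, p in paths.items():
                if key != "dosages_format":
                    manifest.input_digests[key] = _digest(Path(p))
        else:
            sim = SimulationSpec.from_dict({**config.get("simulate", {}), "seed": seed})
            data = simulate_consortium(sim)
            panel, weights, cohort = data.panel, data.weights, data.cohort
        phenotypes = sorted({v.phenotype_tag for v in weights})

    with _Stage(manifest, "pcs"):
        n_pcs = int(config.get("adjust_pcs", 8))
        pcs = None
        if n_pcs > 0:
            pc_df, _ = genotype_pcs(panel, k=n_pcs)
            pcs = pc_df
            pc_df.to_csv(out / "pcs.tsv", sep="\t", na_rep=".")
            manifest.outputs["pcs"] = "pcs.tsv"

    scores = {}
    with _Stage(manifest, "score"):
        std_sample = None
        if config.get("standardization_sample", "all") == "controls":
            std_sample = cohort.data.loc[cohort.data["case"] == 0, "subject_id"]
        for pheno in phenotypes:
            w = weights.subset([v.variant_id for v in weights if v.phenotype_tag == pheno])
            hp = harmonize(panel, w)
            sc = standardize(build_score(hp, w), sample=std_sample)
            q = quintile_groups(sc)
            scores[pheno] = (w, hp, sc, pd.Series(q, index=sc.subject_ids))
            mio.write_weights(w, out / f"weights_{pheno}.tsv")

    with _Stage(manifest, "diagnostics"):
        diagnostics = {}
        for pheno, (w, hp, sc, q) in scores.items():
            entry = {"n_variants": len(w)}
            if pheno in cohort.data.columns:
                ph = cohort.data.set_index("subject_id")[pheno]
                zph = (ph - ph.mean()) / ph.std(ddof=1)
                diag = first_stage(sc.as_series().loc[zph.index].to_numpy(),
                                   zph.to_numpy())
                entry.update(diag.to_dict())
                power_cfg = config.get("power", {})
                or_alt = power_cfg.get("or_alt", {}).get(pheno)
                if or_alt:
                    entry["power"] = mr_power_binary(
                        PowerInput(
                            n_cases=cohort.n_cases,
                            n_controls=cohort.n_controls,
                            r2=diag.r2,
                            or_alt=float(or_alt),
                            alpha=float(power_cfg.get("alpha", 0.05)),
                        )
                    )
            diagnostics[pheno] = entry
        extras["diagnostics"] = diagnostics

    with _Stage(manifest, "confounder_scan"):
        scans = {}
        for pheno, (w, hp, sc, q) in scores.items():
            scan = covariate_scan(sc.as_series(), cohort, cohort.covariate_cols)
            scans[pheno] = scan.to_dict(orient="records")
        extras["covariate_scan"] = scans

    with _Stage(manifest, "reduced_form"):
        rf = {}
        for pheno, (w, hp, sc, q) in scores.items():
            rf[pheno] = {}
            for subset in ("all", "localized", "advanced", "low_grade", "high_grade"):
                est = reduced_form_or(cohort, sc, case_subset=subset)
                est.label = f"{pheno}|{est.label}"
                rows.append(est.to_dict())
                rf[pheno][subset] = est
                if pcs is not None:
                    est_a = reduced_form_or(cohort, sc, case_subset=subset, adjust=pcs)
                    est_a.label = f"{pheno}|{est_a.label}"
                    rows.append(est_a.to_dict())
            est_q = quintile_contrast(cohort, q)
            est_q.label = f"{pheno}|{est_q.label}"
            rows.append(est_q.to_dict())

    with _Stage(manifest, "meta"):
        metas = {}
        for pheno, (w, hp, sc, q) in scores.items():
            meta = per_study_meta(cohort, sc)
            metas[pheno] = {
                "pooled_beta": meta.pooled_beta,
                "pooled_se": meta.pooled_se,
                "q_stat": meta.q_stat,
                "i2": meta.i2,
                "dropped_studies": meta.dropped_studies,
            }
        extras["meta"] = metas

    with _Stage(manifest, "subtype_heterogeneity"):
        het = {}
        for pheno, (w, hp, sc, q) in scores.items():
            het[pheno] = {}
            for axis in ("grade", "stage"):
                e = case_only_heterogeneity(cohort, sc, axis=axis)
                e.label = f"{pheno}|{e.label}"
                rows.append(e.to_dict())
                het[pheno][axis] = e.p
        extras["incidence_heterogeneity_p"] = het

    with _Stage(manifest, "survival"):
        surv = {}
        for pheno, (w, hp, sc, q) in scores.items():
            surv[pheno] = {}
            for event in ("all-cause", "disease-specific"):
                for subset in ("all", "localized", "advanced", "low_grade", "high_grade"):
                    spec = SurvivalSpec(event=event, case_subset=subset)
                    est = cox_effect(spec, cohort, sc)
                    est.label = f"{pheno}|{est.label}"
                    rows.append(est.to_dict())
                    surv[pheno][(event, subset)] = est

    with _Stage(manifest, "survival_heterogeneity"):
        ab = {}
        for pheno in scores:
            ab[pheno] = {}
            for event in ("all-cause", "disease-specific"):
                for pair, (a, b) in {
                    "low_vs_high_grade": ("low_grade", "high_grade"),
                    "localized_vs_advanced": ("localized", "advanced"),
                }.items():
                    h = altman_bland_estimates(
                        surv[pheno][(event, a)], surv[pheno][(event, b)]
                    )
                    ab[pheno][f"{event}:{pair}"] = {"z": h.z, "p": h.p}
        extras["survival_heterogeneity"] = ab

    with _Stage(manifest, "instrument_splits"):
        splits = {}
        for pheno, (w, hp, sc, q) in scores.items():
            mode = "random_halves" if len(w) > 2 else "named_variant_vs_rest"
            e1, e2, h = split_instrument_analysis(
                cohort, panel, w, mode=mode, seed=seed,
                phenotype=pheno if pheno in cohort.data.columns else None,
            )
            for e in (e1, e2):
                e.label = f"{pheno}|split|{e.label}"
                rows.append(e.to_dict())
            splits[pheno] = {"z": h.z, "p": h.p}
        extras["split_heterogeneity"] = splits

    with _Stage(manifest, "rescale"):
        rescaled = []
        for pheno, (w, hp, sc, q) in scores.items():
            cfg = config.get("rescale", {}).get(pheno)
            if cfg is None:
                r2 = diagnostics.get(pheno, {}).get("r2")
                if not r2:
                    continue
                spec = RescaleSpec(r2=r2, unit_sd=1.0)
            else:
                spec = RescaleSpec(r2=float(cfg["r2"]), unit_sd=float(cfg.get("unit_sd", 1.0)))
            targets = [rf[pheno]["all"]] + [
                surv[pheno][(ev, sub)]
                for ev in ("all-cause", "disease-specific")
                for sub in ("low_grade", "high_grade")
            ]
            for est in targets:
                r = wald_rescale(est, spec)
                rows.append(r.to_dict())
                rescaled.append(r.to_dict())
        extras["rescaled"] = rescaled

    with _Stage(manifest, "report"):
        report = pd.DataFrame(rows)
        report.to_csv(out / "report.tsv", sep="\t", index=False, na_rep=".",
                      float_format="%.10g")
        payload = {"results": rows, **_jsonable(extras)}
        (out / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=_coerce), encoding="utf-8"
        )
        manifest.outputs["report_tsv"] = "report.tsv"
        manifest.outputs["report_json"] = "report.json"
        manifest.outputs["digests"] = {
            "report.tsv": _digest(out / "report.tsv"),
            "report.json": _digest(out / "report.json"),
        }

    manifest.completed = True
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True, default=_coerce),
        encoding="utf-8",
    )
    return manifest


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _jsonable(extras: dict) -> dict:
    def conv(x):
        if isinstance(x, dict):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if hasattr(x, "to_dict") and not isinstance(x, (int, float, str)):
            return x.to_dict()
        return x

    return conv(extras)
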