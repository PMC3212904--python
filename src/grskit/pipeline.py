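"""End-to-end orchestration: ingest or simulate, QC, associate, score, evaluate.

A :class:`PipelineConfig` names either real input files (VCF + phenotype +
variant specs) or a simulation block, plus the score panel, weights, cutoff
grid and output directory. :func:`run_pipeline` writes a fixed set of
tab-separated outputs (hwe.tsv, ld.tsv, univariate.tsv, multivariate.tsv,
scores.tsv, thresholds.tsv, roc.tsv, distribution.tsv) and a run.json
provenance record; identical config and seed reproduce identical non-timing
outputs. :func:`recompute_threshold_table` re-derives every classification
metric from published per-cutoff counts alone and flags rows whose printed OR
disagrees with the count cross-product by more than 1%.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import panel as _panel_mod
from .association import multivariate_fit, univariate_table
from .core_data import (GenotypeMatrix, PhenotypeVector, read_genotypes,
                        read_variant_specs)
from .popgen_qc import hwe_table, ld_table
from .risk_score import (classification_metrics, count_score, roc,
                         score_distribution, split_scores, sweep_table,
                         threshold_sweep, weighted_score)
from .synthetic_cohort import CohortSimConfig, simulate_cohort

logger = logging.getLogger("grskit")

OUTPUT_FILES = ["hwe.tsv", "ld.tsv", "univariate.tsv", "multivariate.tsv",
                "scores.tsv", "thresholds.tsv", "roc.tsv", "distribution.tsv",
                "run.json"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source."""

    out_dir: str
    vcf: str | None = None
    phenotype: str | None = None
    variant_specs: str | None = None
    simulation: CohortSimConfig | None = None
    panel: list[str] | None = None          # default: bundled 7-SNP panel
    weights: dict[str, float] | None = None
    cutoffs: list[float] | None = None
    alpha: float = 0.05
    seed: int = 0
    ld_stratum: str = "control"

    def __post_init__(self) -> None:
        file_input = self.vcf is not None
        if file_input == (self.simulation is not None):
            raise ValueError("exactly one of file inputs / simulation block")
        if file_input and (self.phenotype is None or self.variant_specs is None):
            raise ValueError("file input needs vcf, phenotype and variant_specs")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            variants = [  # minimal specs from the sub-block
                _variant_from_dict(d) for d in sim.pop("variants")]
            sim = CohortSimConfig(variants=variants, **sim)
        return cls(simulation=sim, **raw)


def _variant_from_dict(d: dict):
    from .core_data import VariantSpec
    return VariantSpec(**d)


def _load_inputs(config: PipelineConfig
                 ) -> tuple[GenotypeMatrix, PhenotypeVector]:
    if config.simulation is not None:
        return simulate_cohort(config.simulation)
    specs = read_variant_specs(config.variant_specs)
    return read_genotypes(config.vcf, config.phenotype, specs)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
        logger.info("stage output %s: %d rows", name, len(df))

    try:
        gm, ph = _load_inputs(config)
        logger.info("cohort: %d cases / %d controls, %d SNPs",
                    ph.n_case, ph.n_control, len(gm.variants))

        emit("hwe.tsv", hwe_table(gm, ph, stratum=config.ld_stratum))
        emit("ld.tsv", ld_table(gm, ph, stratum=config.ld_stratum))
        emit("univariate.tsv", univariate_table(gm, ph))

        panel = config.panel
        if panel is None:
            available = set(gm.snp_ids)
            panel = [v.snp_id for v in _panel_mod.significant_panel()
                     if v.snp_id in available]
        if not panel:
            raise RuntimeError("score panel is empty")
        _, multi = multivariate_fit(gm, ph, panel)
        emit("multivariate.tsv", multi)

        cs = count_score(gm, panel)
        ws = weighted_score(gm, panel, config.weights)
        emit("scores.tsv", pd.DataFrame({
            "sample_id": cs.sample_ids,
            "status": [int(x) for x in
                       (dict(zip(ph.sample_ids, ph.is_case))[s]
                        for s in cs.sample_ids)],
            "count_score": cs.score, "weighted_score": ws.score,
            "imputed": cs.imputed}))

        rows = []
        roc_rows = []
        dist_rows = []
        for profile in (cs, ws):
            case, ctrl = split_scores(profile, ph)
            if config.cutoffs is not None:
                cuts = np.asarray(config.cutoffs, dtype=float)
            elif profile.score_type == "count":
                cuts = np.unique(np.concatenate([case, ctrl]))
            else:
                lo = int(np.floor(min(case.min(), ctrl.min())))
                hi = int(np.ceil(max(case.max(), ctrl.max())))
                cuts = np.arange(lo, hi + 1, dtype=float)
            tab = sweep_table(threshold_sweep(case, ctrl, cuts))
            tab.insert(0, "score_type", profile.score_type)
            rows.append(tab)
            curve = roc(case, ctrl)
            rc = pd.DataFrame(curve.points, columns=["fpr", "sensitivity"])
            rc.insert(0, "score_type", profile.score_type)
            rc["auc"] = curve.auc
            roc_rows.append(rc)
            edges = np.arange(np.floor(min(case.min(), ctrl.min())),
                              np.ceil(max(case.max(), ctrl.max())) + 1.0)
            if edges.size < 2:
                edges = np.array([0.0, 1.0])
            dist = score_distribution(profile, ph, edges)
            dist.insert(0, "score_type", profile.score_type)
            dist_rows.append(dist)
        emit("thresholds.tsv", pd.concat(rows, ignore_index=True))
        emit("roc.tsv", pd.concat(roc_rows, ignore_index=True))
        emit("distribution.tsv", pd.concat(dist_rows, ignore_index=True))

        run_meta = {
            "config": _config_dict(config),
            "seed": config.seed,
            "n_case": ph.n_case, "n_control": ph.n_control,
            "panel": panel,
            "elapsed_s": round(time.time() - t0, 3),
        }
        (out / "run.json").write_text(json.dumps(run_meta, indent=2))
        written["run.json"] = out / "run.json"
    except Exception:
        # remove partial outputs so a failed run leaves no half-report
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return written


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("simulation") is not None:
        d["simulation"]["variants"] = [v["snp_id"]
                                       for v in d["simulation"]["variants"]]
    return d


def recompute_threshold_table(counts: pd.DataFrame | str | Path,
                              or_tolerance: float = 0.01) -> pd.DataFrame:
    """Re-derive all classification metrics from per-cutoff counts alone.

    ``counts`` is a table (or TSV path) with columns cutoff, n_case_ge,
    n_control_ge, n_cases, n_controls and optionally printed_or. Every metric
    column is recomputed through :func:`classification_metrics`; when a
    printed OR is supplied, rows whose recomputed OR differs by more than
    ``or_tolerance`` (relative) are flagged ``inconsistent`` — this exposes
    published rows whose OR cannot be the cross-product of their own counts.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.read_csv(counts, sep="\t")
    required = {"cutoff", "n_case_ge", "n_control_ge", "n_cases", "n_controls"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    rows = []
    for rec in counts.to_dict("records"):
        ev = classification_metrics(int(rec["n_case_ge"]), int(rec["n_cases"]),
                                    int(rec["n_control_ge"]),
                                    int(rec["n_controls"]),
                                    cutoff=float(rec["cutoff"]))
        row = {"cutoff": ev.cutoff, "n_case_ge": ev.n_case_ge,
               "n_control_ge": ev.n_control_ge, "or": ev.or_point,
               "ci_low": ev.ci_low, "ci_high": ev.ci_high,
               "p_value": ev.p_value, "sensitivity": ev.sensitivity,
               "specificity": ev.specificity, "ppv": ev.ppv, "npv": ev.npv,
               "accuracy": ev.accuracy, "haldane": ev.haldane}
        if "printed_or" in rec and not pd.isna(rec["printed_or"]):
            rel = abs(ev.or_point - rec["printed_or"]) / rec["printed_or"]
            row["printed_or"] = rec["printed_or"]
            row["inconsistent"] = bool(rel > or_tolerance)
        rows.append(row)
    return pd.DataFrame(rows)
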