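"""End-to-end pipeline: simulate -> quantify -> select -> analyze -> classify.

Each stage writes its artifacts into the output directory and records its
filter counts in a manifest (config hash, seed, package versions, stage
outputs), mirroring the audit trail a real-data rerun needs.  A stage
failure aborts with the failing stage named; earlier outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ContingencyReport, SvmConfig, features_from_matrix,
                       merge_class_report, nested_cv, predict_cohort,
                       probability_by_grade, train_final)
from .errors import StageError
from .io import (RunConfig, write_metadata, write_signal_matrix,
                 write_trace_table)
from .peaks import build_signal_matrix
from .selection import correlations_to_frame, run_selection
from .stats import count_significant, hierarchical_cluster, log2_transform, \
    pairwise_ttests
from .synthetic_data import generate_cohort, generate_validation_cohort

log = logging.getLogger("digiwest.pipeline")

__all__ = ["run_pipeline", "config_hash"]


class _SkipStage(Exception):
    """Internal: the stage finished early with a degenerate (empty) input."""


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "digiwest", "version": __version__,
        "seed": config.seed, "config_hash": config_hash(config),
        "config": config.model_dump(), "stages": {},
    }

    def finish_stage(name: str, outputs: list[str], counts: dict) -> None:
        manifest["stages"][name] = {"outputs": outputs, "counts": counts}
        log.info("stage %s done: %s", name, counts)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    # ---- simulate -----------------------------------------------------
    try:
        cc = config.simulate.to_cohort_config(config.seed)
        ff, ffpe, meta, truth = generate_cohort(cc)
        val, val_meta = generate_validation_cohort(cc, truth)
        outputs = []
        write_metadata(meta, out / "metadata.tsv")
        write_metadata(val_meta, out / "metadata_validation.tsv")
        truth.antibodies.to_csv(out / "ground_truth_antibodies.tsv", sep="\t",
                                index=False)
        outputs += ["metadata.tsv", "metadata_validation.tsv",
                    "ground_truth_antibodies.tsv"]
        if config.write_traces:
            write_trace_table(ff, out / "traces_ff.tsv")
            write_trace_table(ffpe, out / "traces_ffpe.tsv")
            write_trace_table(val, out / "traces_validation.tsv")
            outputs += ["traces_ff.tsv", "traces_ffpe.tsv", "traces_validation.tsv"]
        finish_stage("simulate", outputs,
                     {"n_antibodies": cc.n_antibodies, "n_ff": len(ff.sample_ids),
                      "n_ffpe": len(ffpe.sample_ids),
                      "n_validation": len(val.sample_ids)})
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e

    # ---- quantify -----------------------------------------------------
    try:
        qc = config.quantify.to_quant_config()
        ann = truth.antibodies
        m_ff = build_signal_matrix(ff, ann, qc)
        m_ffpe = build_signal_matrix(ffpe, ann, qc)
        m_val = build_signal_matrix(val, ann, qc)
        for name, m in (("signals_ff", m_ff), ("signals_ffpe", m_ffpe),
                        ("signals_validation", m_val)):
            write_signal_matrix(m, out / f"{name}.tsv")
        finish_stage("quantify",
                     [f"signals_{k}.tsv" for k in ("ff", "ffpe", "validation")],
                     {"signals_ff": len(m_ff.signal_ids),
                      "signals_ffpe": len(m_ffpe.signal_ids),
                      "signals_validation": len(m_val.signal_ids),
                      "mean_detected_ff": float(
                          m_ff.antibody_detection().sum(axis=1).mean()),
                      "mean_detected_ffpe": float(
                          m_ffpe.antibody_detection().sum(axis=1).mean())})
    except Exception as e:  # noqa: BLE001
        raise StageError("quantify", str(e)) from e

    # ---- select -------------------------------------------------------
    try:
        l_ff = log2_transform(m_ff, config.log2_floor)
        l_ffpe = log2_transform(m_ffpe, config.log2_floor)
        manual = sorted(truth.antibodies.loc[truth.antibodies.crossreact,
                                             "antibody_id"])
        sel = run_selection(l_ff, l_ffpe, meta, manual_excludes=manual,
                            alpha=config.select.alpha,
                            min_detected=config.select.min_detected,
                            min_pairs=config.select.min_pairs)
        (out / "selection.json").write_text(json.dumps({
            "stage_counts": sel.stage_counts,
            "dispositions": sel.dispositions,
            "panel": sel.panel}, indent=1))
        correlations_to_frame(sel.correlations).to_csv(out / "volcano.tsv",
                                                       sep="\t", index=False)
        finish_stage("select", ["selection.json", "volcano.tsv"], sel.stage_counts)
    except Exception as e:  # noqa: BLE001
        raise StageError("select", str(e)) from e

    # ---- analyze ------------------------------------------------------
    try:
        panel_signals = [s for _, s in sel.panel]
        p_ff = [s for s in panel_signals if s in l_ff.values.index]
        p_ffpe = [s for s in panel_signals if s in l_ffpe.values.index]
        if p_ff and p_ffpe:
            tree_ff = hierarchical_cluster(l_ff.subset_signals(p_ff))
            tree_ffpe = hierarchical_cluster(l_ffpe.subset_signals(p_ffpe))
            (out / "cluster_ff.nwk").write_text(tree_ff.to_newick() + "\n")
            (out / "cluster_ffpe.nwk").write_text(tree_ffpe.to_newick() + "\n")
        shared = [s for s in panel_signals
                  if s in l_ff.values.index and s in l_ffpe.values.index]
        if not shared:
            finish_stage("analyze", [], {"panel_size": 0, "significant_ff": 0,
                                         "significant_ffpe": 0})
            raise _SkipStage
        tt_ff = pairwise_ttests(l_ff, meta, panel=shared,
                                alpha=config.stats.alpha,
                                bh_scope=config.stats.bh_scope,
                                welch=config.stats.welch)
        tt_ffpe = pairwise_ttests(l_ffpe, meta, panel=shared,
                                  alpha=config.stats.alpha,
                                  bh_scope=config.stats.bh_scope,
                                  welch=config.stats.welch)
        tt_ff.p_bh.to_csv(out / "ttests_ff.tsv", sep="\t", na_rep="NA")
        tt_ffpe.p_bh.to_csv(out / "ttests_ffpe.tsv", sep="\t", na_rep="NA")
        counts = count_significant(tt_ff, tt_ffpe)
        counts.to_csv(out / "significant_counts.tsv", sep="\t")
        finish_stage("analyze",
                     ["cluster_ff.nwk", "cluster_ffpe.nwk", "ttests_ff.tsv",
                      "ttests_ffpe.tsv", "significant_counts.tsv"],
                     {"panel_size": len(panel_signals),
                      "significant_ff": int(counts["n_ff"].sum()),
                      "significant_ffpe": int(counts["n_ffpe"].sum())})
    except _SkipStage:
        pass
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze", str(e)) from e

    # ---- classify -----------------------------------------------------
    try:
        if not p_ff or not p_ffpe:
            raise ValueError("no features: the selected panel is empty")
        svm = SvmConfig(C_grid=tuple(config.classify.C_grid),
                        sigma_grid=tuple(config.classify.sigma_grid),
                        outer_folds=config.classify.outer_folds,
                        outer_repeats=config.classify.outer_repeats,
                        inner_folds=config.classify.inner_folds,
                        inner_repeats=config.classify.inner_repeats,
                        seed=config.seed,
                        standardize=config.classify.standardize,
                        probability=config.classify.probability)
        meta_idx = meta.set_index("sample_id")
        reports = {}
        for name, mat, sigs in (("ff", l_ff, p_ff), ("ffpe", l_ffpe, p_ffpe)):
            X = features_from_matrix(mat, sigs)
            y = meta_idx.loc[X.index, "tumor_type"].tolist()
            reports[name] = nested_cv(X, y, svm)
        lung_merge = {c: ("LUNG" if c in ("LUSC", "LUAD") else c)
                      for c in reports["ffpe"].matrix.index}
        merged = merge_class_report(reports["ffpe"], lung_merge)
        X_train = features_from_matrix(l_ffpe, p_ffpe)
        y_train = meta_idx.loc[X_train.index, "tumor_type"].tolist()
        model = train_final(X_train, y_train, svm)
        l_val = log2_transform(m_val, config.log2_floor)
        # the validation cohort is quantified independently; align its signal
        # rows to the training panel by signal id, absent rows stay missing
        X_val = pd.DataFrame(np.nan, index=l_val.values.columns, columns=p_ffpe)
        for s in p_ffpe:
            if s in l_val.values.index:
                X_val[s] = l_val.values.loc[s]
        records = predict_cohort(model, X_val, val_meta)
        val_acc = 100.0 * float((records["predicted_type"] ==
                                 records["true_type"]).mean())
        grade = probability_by_grade(records)
        report_json = {
            name: {"matrix": rep.matrix.to_dict(), "accuracy_mean": rep.accuracy_mean,
                   "accuracy_sd": rep.accuracy_sd,
                   "per_class": rep.per_class.to_dict()}
            for name, rep in {**reports, "ffpe_lung_merged": merged}.items()}
        report_json["validation"] = {"accuracy": val_acc,
                                     "C": model.C, "sigma": model.sigma,
                                     "probability_by_grade": grade}
        (out / "classification.json").write_text(json.dumps(report_json, indent=1))
        records.to_csv(out / "predictions_validation.tsv", sep="\t")
        finish_stage("classify",
                     ["classification.json", "predictions_validation.tsv"],
                     {"accuracy_ff": reports["ff"].accuracy_mean,
                      "accuracy_ffpe": reports["ffpe"].accuracy_mean,
                      "accuracy_ffpe_lung_merged": merged.accuracy_mean,
                      "accuracy_validation": val_acc})
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", str(e)) from e

    return manifest
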