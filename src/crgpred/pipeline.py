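"""End-to-end training and blinded prediction.

``run_train`` executes preprocessing, the LOOCV grid search and winner
selection on a labeled training cohort, then freezes the chosen
configuration (signature, training reference vectors, algorithm) to a
versioned JSON artifact.  ``run_predict`` applies a frozen model plus a
hybrid clinical strategy to a new cohort; predictions are computed and
written before outcome labels are ever consulted, so blinded validation
is structurally enforced, and evaluation (confusion metrics, ROC,
Kaplan-Meier comparison) runs only when outcomes are present.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import clinical as clinical_rules
from .classify import TrainingReference, predict, score_with
from .data_model import (
    CtMatrix,
    Prediction,
    RECURRENT,
    read_clinical_table,
    read_ct_table,
    write_predictions,
)
from .evaluate import (
    ConfusionCounts,
    compare_survival,
    confusion_metrics,
    roc_by_modifier,
)
from .model_selection import evaluate_grid, pick_winner
from .preprocess import impute_nondetects, normalize_to_reference, substitute_ceiling
from .signature import select_signature

__all__ = ["PipelineConfig", "run_train", "run_predict", "load_model", "save_model"]

logger = logging.getLogger(__name__)

MODEL_VERSION = 1


@dataclass
class PipelineConfig:
    """File paths and tunables for one train or predict run."""

    ct_path: str
    clinical_path: str
    out_dir: str
    reference_gene: str = "BECN1"
    nondetect_token: str = "ND"
    max_cycle: float = 40.0
    imputation: str = "em"          # {em, ceiling, none}
    t_variant: str = "welch"
    p_cutoffs: Sequence[float] = (0.01, 0.02, 0.05, 0.10, 0.20)
    algorithms: Sequence[str] = ("centroid", "distance", "nearest_neighbor")
    selection_mode: str = "full_set"
    distance_normalization: str = "mean"
    strategy: int = 5
    require_negative_margins: bool = True
    sample_ids: Optional[Sequence[str]] = None   # restrict to a split
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _log_tunables(cfg: PipelineConfig, stage: str) -> None:
    logger.info(
        "%s: reference_gene=%s imputation=%s t_variant=%s p_cutoffs=%s "
        "algorithms=%s selection_mode=%s strategy=%s seed=%s",
        stage, cfg.reference_gene, cfg.imputation, cfg.t_variant,
        list(cfg.p_cutoffs), list(cfg.algorithms), cfg.selection_mode,
        cfg.strategy, cfg.seed,
    )


def _load_inputs(cfg: PipelineConfig):
    try:
        ct = read_ct_table(cfg.ct_path, cfg.nondetect_token)
    except Exception as exc:
        raise RuntimeError(f"[data_model stage] reading Ct table failed: {exc}") from exc
    records = read_clinical_table(cfg.clinical_path)
    if cfg.sample_ids is not None:
        wanted = list(cfg.sample_ids)
        ct = ct.subset_samples(wanted)
        by_id = {r.sample_id: r for r in records}
        records = [by_id[s] for s in wanted]
    return ct, records


def _expression_matrices(ct: CtMatrix, cfg: PipelineConfig, labels=None):
    """Imputed and/or ceiling-substituted expression per the config."""
    try:
        expr_unimputed = normalize_to_reference(
            substitute_ceiling(ct, cfg.max_cycle), cfg.reference_gene
        )
        if cfg.imputation == "em":
            expr_imputed, model = impute_nondetects(
                ct, cfg.reference_gene, labels=labels, seed=cfg.seed
            )
        elif cfg.imputation in ("ceiling", "none"):
            expr_imputed, model = None, None
        else:
            raise ValueError(f"unknown imputation mode {cfg.imputation!r}")
    except (KeyError, ValueError) as exc:
        raise RuntimeError(f"[preprocess stage] {exc}") from exc
    return expr_imputed, expr_unimputed, model


def save_model(path, model: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model, fh, indent=1)


def load_model(path) -> dict:
    with open(path) as fh:
        model = json.load(fh)
    if model.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model version {model.get('version')!r}")
    return model


def _write_grid_reports(out_dir: Path, cells, marginals) -> None:
    with open(out_dir / "grid.tsv", "w", encoding="utf-8") as fh:
        fh.write("data_handling\tp_cutoff\talgorithm\taccuracy\tsensitivity\t"
                 "specificity\tsignature_size\tempty_signature_folds\n")
        for c in cells:
            fh.write(f"{c.data_handling}\t{c.p_cutoff}\t{c.algorithm}\t"
                     f"{c.accuracy}\t{c.sensitivity}\t{c.specificity}\t"
                     f"{c.signature_size}\t{len(c.empty_signature_folds)}\n")
    with open(out_dir / "grid_marginals.tsv", "w", encoding="utf-8") as fh:
        fh.write("axis\tlevel\t" + "\t".join(
            f"acc_at_{c}" for c in marginals["p_cutoffs"]) + "\tauc\n")
        for axis in ("by_handling", "by_algorithm"):
            for level, summary in marginals[axis].items():
                fh.write(f"{axis}\t{level}\t" + "\t".join(
                    f"{v}" for v in summary["curve"]) + f"\t{summary['auc']}\n")
        bp = marginals["best_pair"]
        fh.write("best_pair\t" + f"{bp['data_handling']}+{bp['algorithm']}\t"
                 + "\t".join(f"{v}" for v in bp["curve"]) + f"\t{bp['auc']}\n")


def run_train(cfg: PipelineConfig) -> dict:
    """Grid search on the training cohort; returns and freezes the winner."""
    _log_tunables(cfg, "train")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ct, records = _load_inputs(cfg)
    labels = {r.sample_id: r.recurred for r in records}
    unknown = [s for s, v in labels.items() if v is None]
    if unknown:
        raise ValueError(f"training labels unknown for samples: {unknown}")

    expr_imputed, expr_unimputed, _ = _expression_matrices(ct, cfg, labels=labels)
    if expr_imputed is None:
        expr_imputed = expr_unimputed
    cells, marginals = evaluate_grid(
        expr_imputed, expr_unimputed, labels,
        p_cutoffs=cfg.p_cutoffs, algorithms=cfg.algorithms,
        selection_mode=cfg.selection_mode, t_variant=cfg.t_variant,
    )
    winner = pick_winner(cells)
    expr_win = expr_imputed if winner.data_handling == "imputed" else expr_unimputed
    signature = select_signature(expr_win, labels, winner.p_cutoff, variant=cfg.t_variant)
    ref = TrainingReference.from_expression(expr_win, labels, signature.gene_ids)
    logger.info(
        "winner: handling=%s cutoff=%s algorithm=%s accuracy=%.3f signature=%s",
        winner.data_handling, winner.p_cutoff, winner.algorithm,
        winner.accuracy, signature.gene_ids,
    )

    model = {
        "version": MODEL_VERSION,
        "reference_gene": cfg.reference_gene,
        "max_cycle": cfg.max_cycle,
        "imputation": cfg.imputation if winner.data_handling == "imputed" else "ceiling",
        "data_handling": winner.data_handling,
        "algorithm": winner.algorithm,
        "distance_normalization": cfg.distance_normalization,
        "p_cutoff": winner.p_cutoff,
        "t_variant": cfg.t_variant,
        "loocv": {
            "accuracy": winner.accuracy,
            "sensitivity": winner.sensitivity,
            "specificity": winner.specificity,
        },
        "signature": {
            "gene_ids": signature.gene_ids,
            "p_cutoff": signature.p_cutoff,
            "results": [dataclasses.asdict(r) for r in signature.results],
        },
        "training_reference": {
            "gene_ids": ref.signature_gene_ids,
            "recurrent_vectors": ref.recurrent_vectors.tolist(),
            "nonrecurrent_vectors": ref.nonrecurrent_vectors.tolist(),
        },
    }
    save_model(out_dir / "model.json", model)
    _write_grid_reports(out_dir, cells, marginals)
    with open(out_dir / "signature.tsv", "w", encoding="utf-8") as fh:
        fh.write("# raw p-value cutoff used as a tuning parameter; "
                 "no multiple-testing correction applied\n")
        fh.write("gene\tmean_recurrent\tmean_nonrecurrent\tt\tp\tsigned_fold_change\n")
        for r in signature.results:
            fh.write(f"{r.gene_id}\t{r.mean_recurrent}\t{r.mean_nonrecurrent}\t"
                     f"{r.t_statistic}\t{r.p_value}\t{r.signed_fold_change}\n")
    return {"winner": winner, "model": model, "cells": cells, "marginals": marginals}


def _crg_score_pairs(ct: CtMatrix, model: dict, cfg: PipelineConfig):
    ref = TrainingReference(
        signature_gene_ids=list(model["training_reference"]["gene_ids"]),
        recurrent_vectors=np.array(model["training_reference"]["recurrent_vectors"]),
        nonrecurrent_vectors=np.array(model["training_reference"]["nonrecurrent_vectors"]),
    )
    missing = [g for g in ref.signature_gene_ids if g not in ct.gene_ids]
    if missing:
        raise ValueError(f"signature gene(s) absent from query matrix: {missing}")
    if model["data_handling"] == "imputed":
        expr, _ = impute_nondetects(ct, model["reference_gene"], seed=cfg.seed)
    else:
        expr = normalize_to_reference(
            substitute_ceiling(ct, model["max_cycle"]), model["reference_gene"]
        )
    pairs = {}
    for sid in expr.sample_ids:
        x = expr.sample_vector(sid, ref.signature_gene_ids)
        pairs[sid] = score_with(
            model["algorithm"], ref, x, sid,
            distance_normalization=model.get("distance_normalization", "mean"),
        )
    return pairs


def run_predict(cfg: PipelineConfig, model_path) -> dict:
    """Apply a frozen model + clinical strategy; evaluate when unblinded.

    Predictions are derived from expression and staging only and written
    to disk before any outcome column is read.
    """
    _log_tunables(cfg, "predict")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = load_model(model_path)
    ct, records = _load_inputs(cfg)

    needs_crg = cfg.strategy in (1, 5, 6)
    score_pairs = _crg_score_pairs(ct, model, cfg) if needs_crg else {}
    crg_labels = {sid: predict(pair) for sid, pair in score_pairs.items()}
    strat = clinical_rules.run_strategy(
        cfg.strategy, records, crg_predictions=crg_labels or None,
        require_negative_margins=cfg.require_negative_margins,
    )
    predictions = [
        Prediction(
            sample_id=r.sample_id,
            predicted=strat.labels[r.sample_id],
            recurrence_score=(score_pairs[r.sample_id].recurrence_score
                              if r.sample_id in score_pairs else None),
            nonrecurrence_score=(score_pairs[r.sample_id].nonrecurrence_score
                                 if r.sample_id in score_pairs else None),
            strategy=strat.strategy,
        )
        for r in records
    ]
    write_predictions(out_dir / "predictions.tsv", predictions)

    # ---- evaluation: only now may outcome labels be read -----------------
    known = [r for r in records if r.recurred is not None]
    result = {"predictions": predictions, "strategy": strat, "metrics": None}
    if not known:
        return result
    truth = {r.sample_id: bool(r.recurred) for r in known}
    predicted = {r.sample_id: strat.labels[r.sample_id] for r in known}
    counts = ConfusionCounts.from_predictions(predicted, truth)
    metrics = confusion_metrics(counts)
    result["counts"] = counts
    result["metrics"] = metrics
    with open(out_dir / "metrics.tsv", "w", encoding="utf-8") as fh:
        fh.write("strategy\t" + "\t".join(metrics) + "\n")
        fh.write(strat.strategy + "\t" + "\t".join(
            "NA" if v is None else f"{v}" for v in metrics.values()) + "\n")

    evaluable = [p for p in score_pairs.values() if p.sample_id in truth]
    if evaluable and len({truth[p.sample_id] for p in evaluable}) == 2:
        roc = roc_by_modifier(evaluable, truth)
        result["roc"] = roc
        with open(out_dir / "roc.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# auc\t{roc.auc}\nmodifier\tfpr\ttpr\n")
            for m, fpr, tpr in roc.points:
                fh.write(f"{m}\t{fpr}\t{tpr}\n")

    pred_rec = [r for r in known if strat.labels[r.sample_id] == RECURRENT]
    pred_non = [r for r in known if strat.labels[r.sample_id] != RECURRENT]
    if pred_rec and pred_non and any(r.recurred for r in known):
        surv = compare_survival(
            [r.time_to_event for r in pred_rec], [bool(r.recurred) for r in pred_rec],
            [r.time_to_event for r in pred_non], [bool(r.recurred) for r in pred_non],
        )
        result["survival"] = surv
        for name, curve in (("km_predicted_recurrent.tsv", surv.curve_a),
                            ("km_predicted_nonrecurrent.tsv", surv.curve_b)):
            with open(out_dir / name, "w", encoding="utf-8") as fh:
                fh.write(f"# logrank_chi_square\t{surv.chi_square}\n"
                         f"# logrank_p\t{surv.p_value}\ntime_months\tsurvival\n")
                for t, s in zip(curve.times, curve.survival):
                    fh.write(f"{t}\t{s}\n")
    return result
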