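"""Leave-one-out cross-validation over data handling x p-cutoff x algorithm.

Each grid cell holds one configuration's LOOCV confusion metrics on the
training cohort.  Two signature-selection modes are provided:

* ``full_set`` — the signature is selected once on the full
  training set and reused in every fold.  This lets the held-out sample
  influence gene selection and therefore inflates LOOCV accuracy; it is
  retained because it mirrors a common (if optimistic) practice.
* ``nested`` — the signature is re-selected inside each fold from the
  remaining samples only (no leakage); folds whose signature is empty
  fall back to the tie-rule label (recurrent) and are flagged.

``nested`` is the recommended mode; ``full_set`` is the default for
continuity with the grid-search protocol this pipeline reproduces, and a
warning is logged whenever it is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .classify import TrainingReference, predict, score_with
from .data_model import ExpressionMatrix, RECURRENT
from .signature import EmptySignatureError, select_signature

__all__ = ["GridCell", "loocv", "evaluate_grid", "pick_winner"]

logger = logging.getLogger(__name__)

_ALGORITHM_ORDER = ("centroid", "distance", "nearest_neighbor")
_HANDLING_ORDER = ("imputed", "unimputed")


@dataclass
class GridCell:
    """One (data handling, p-cutoff, algorithm) configuration's LOOCV result."""

    data_handling: str
    p_cutoff: float
    algorithm: str
    accuracy: float
    sensitivity: float
    specificity: float
    fold_predictions: dict[str, str] = field(default_factory=dict)
    signature_size: Optional[int] = None
    empty_signature_folds: list[str] = field(default_factory=list)
    selection_mode: str = "full_set"


def _fold_metrics(fold_predictions: Mapping[str, str], labels: Mapping[str, bool]):
    tp = sum(1 for s, p in fold_predictions.items() if labels[s] and p == RECURRENT)
    fn = sum(1 for s, p in fold_predictions.items() if labels[s] and p != RECURRENT)
    tn = sum(1 for s, p in fold_predictions.items() if not labels[s] and p != RECURRENT)
    fp = sum(1 for s, p in fold_predictions.items() if not labels[s] and p == RECURRENT)
    total = tp + fn + tn + fp
    return (
        (tp + tn) / total,
        tp / (tp + fn) if (tp + fn) else float("nan"),
        tn / (tn + fp) if (tn + fp) else float("nan"),
    )


def loocv(
    expr: ExpressionMatrix,
    labels: Mapping[str, bool],
    p_cutoff: float,
    algorithm: str,
    selection_mode: str = "full_set",
    t_variant: str = "welch",
    distance_normalization: str = "mean",
    data_handling: str = "",
) -> GridCell:
    """LOOCV of one configuration; one fold per training sample.

    Raises ``ValueError`` if either class has fewer than 2 samples (a
    fold could otherwise empty a group).
    """
    if selection_mode not in ("full_set", "nested"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    sample_ids = list(expr.sample_ids)
    n_rec = sum(bool(labels[s]) for s in sample_ids)
    if n_rec < 2 or len(sample_ids) - n_rec < 2:
        raise ValueError("each class needs >= 2 samples for LOOCV")
    if selection_mode == "full_set":
        logger.warning(
            "full_set mode selects the signature on the full training "
            "set; LOOCV estimates will be optimistic (use nested to avoid leakage)"
        )

    full_signature = None
    signature_size: Optional[int] = None
    if selection_mode == "full_set":
        try:
            full_signature = select_signature(expr, labels, p_cutoff, variant=t_variant)
            signature_size = len(full_signature)
        except EmptySignatureError:
            full_signature = None
            signature_size = 0

    fold_predictions: dict[str, str] = {}
    empty_folds: list[str] = []
    for held_out in sample_ids:
        rest = [s for s in sample_ids if s != held_out]
        train = expr.subset_samples(rest)
        if selection_mode == "full_set":
            sig = full_signature
        else:
            try:
                sig = select_signature(train, labels, p_cutoff, variant=t_variant)
            except EmptySignatureError:
                sig = None
        if sig is None:
            fold_predictions[held_out] = RECURRENT  # tie-rule fallback
            empty_folds.append(held_out)
            continue
        ref = TrainingReference.from_expression(train, labels, sig.gene_ids)
        x = expr.sample_vector(held_out, sig.gene_ids)
        pair = score_with(algorithm, ref, x, held_out,
                          distance_normalization=distance_normalization)
        fold_predictions[held_out] = predict(pair)

    acc, sens, spec = _fold_metrics(fold_predictions, labels)
    return GridCell(
        data_handling=data_handling or expr.provenance,
        p_cutoff=p_cutoff,
        algorithm=algorithm,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        fold_predictions=fold_predictions,
        signature_size=signature_size,
        empty_signature_folds=empty_folds,
        selection_mode=selection_mode,
    )


def evaluate_grid(
    expr_imputed: ExpressionMatrix,
    expr_unimputed: ExpressionMatrix,
    labels: Mapping[str, bool],
    p_cutoffs: Sequence[float] = (0.01, 0.02, 0.05, 0.10, 0.20),
    algorithms: Sequence[str] = _ALGORITHM_ORDER,
    selection_mode: str = "full_set",
    t_variant: str = "welch",
) -> tuple[list[GridCell], dict]:
    """Evaluate every handling x cutoff x algorithm combination.

    Returns the grid cells plus marginal summaries: mean accuracy over
    algorithms per data handling (with trapezoidal area under the curve
    along the cutoff axis), mean over handlings per algorithm, and the
    cutoff curve of the single best handling+algorithm pair.
    """
    if not p_cutoffs or not algorithms:
        raise ValueError("p_cutoffs and algorithms must be non-empty")
    handled = {"imputed": expr_imputed, "unimputed": expr_unimputed}
    cells: list[GridCell] = []
    for handling, expr in handled.items():
        for cutoff in p_cutoffs:
            for alg in algorithms:
                cells.append(loocv(
                    expr, labels, cutoff, alg,
                    selection_mode=selection_mode, t_variant=t_variant,
                    data_handling=handling,
                ))

    def _curve(subset: list[GridCell]) -> list[float]:
        return [
            float(np.mean([c.accuracy for c in subset if c.p_cutoff == cut]))
            for cut in p_cutoffs
        ]

    cutoffs = np.asarray(p_cutoffs, float)
    by_handling = {}
    for handling in handled:
        curve = _curve([c for c in cells if c.data_handling == handling])
        by_handling[handling] = {
            "curve": curve,
            "auc": float(np.trapezoid(curve, cutoffs)),
            "mean_accuracy": float(np.mean(curve)),
        }
    by_algorithm = {}
    for alg in algorithms:
        curve = _curve([c for c in cells if c.algorithm == alg])
        by_algorithm[alg] = {
            "curve": curve,
            "auc": float(np.trapezoid(curve, cutoffs)),
            "mean_accuracy": float(np.mean(curve)),
        }

    # best single handling+algorithm pair (by mean accuracy across cutoffs)
    best_pair, best_mean, best_curve = None, -np.inf, None
    for handling in _HANDLING_ORDER:
        if handling not in handled:
            continue
        for alg in algorithms:
            curve = _curve([
                c for c in cells
                if c.data_handling == handling and c.algorithm == alg
            ])
            m = float(np.mean(curve))
            if m > best_mean:
                best_pair, best_mean, best_curve = (handling, alg), m, curve
    marginals = {
        "p_cutoffs": list(p_cutoffs),
        "by_handling": by_handling,
        "by_algorithm": by_algorithm,
        "best_pair": {
            "data_handling": best_pair[0],
            "algorithm": best_pair[1],
            "curve": best_curve,
            "auc": float(np.trapezoid(best_curve, cutoffs)),
        },
    }
    return cells, marginals


def pick_winner(grid: Sequence[GridCell]) -> GridCell:
    """Deterministic winner: highest accuracy, ties broken by higher
    sensitivity, smaller signature, then algorithm order (centroid,
    distance, nearest neighbor) and data handling (imputed first)."""
    if not grid:
        raise ValueError("empty grid")

    def key(c: GridCell):
        sens = -1.0 if np.isnan(c.sensitivity) else c.sensitivity
        size = c.signature_size if c.signature_size is not None else np.inf
        alg = _ALGORITHM_ORDER.index(c.algorithm) if c.algorithm in _ALGORITHM_ORDER else 99
        handling = (
            _HANDLING_ORDER.index(c.data_handling)
            if c.data_handling in _HANDLING_ORDER else 99
        )
        return (-c.accuracy, -sens, size, alg, handling)

    return min(grid, key=key)
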