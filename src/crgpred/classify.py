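"""Signature-space scoring algorithms and the recurrence decision rule.

Each query sample is a point in signature space (one axis per signature
gene, log2 expression units).  Three scorers compare it with the labeled
training vectors:

* ``distance`` — mean Euclidean distance to all members of each group;
* ``centroid`` — Euclidean distance to each group's arithmetic centroid;
* ``nearest_neighbor`` — Euclidean distance to the closest group member.

The base decision takes the group with the lower score; ties go to
recurrent, which favors sensitivity (a missed recurrence withholds
adjuvant therapy from a patient who needs it).  An additive modifier
shifts the decision margin to sweep ROC operating points: at +10 every
sample is called recurrent, at -10 none is.

The ``distance`` sum grows with group size, so with unbalanced groups a
raw sum would systematically disfavor the larger group; scores are
therefore averaged within group by default (``normalization="mean"``),
with ``"raw_sum"`` available for the balanced-cohort convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import ExpressionMatrix, NONRECURRENT, RECURRENT

__all__ = [
    "TrainingReference",
    "ScorePair",
    "score_distance",
    "score_centroid",
    "score_nearest_neighbor",
    "predict",
    "score_with",
    "ALGORITHMS",
]


@dataclass
class TrainingReference:
    """Labeled training vectors restricted to the signature genes."""

    signature_gene_ids: list[str]
    recurrent_vectors: np.ndarray      # N_r x I
    nonrecurrent_vectors: np.ndarray   # N_nr x I

    def __post_init__(self) -> None:
        self.recurrent_vectors = np.atleast_2d(np.asarray(self.recurrent_vectors, float))
        self.nonrecurrent_vectors = np.atleast_2d(np.asarray(self.nonrecurrent_vectors, float))
        i = len(self.signature_gene_ids)
        if i < 1:
            raise ValueError("signature must contain at least one gene")
        if self.recurrent_vectors.shape[0] < 1 or self.nonrecurrent_vectors.shape[0] < 1:
            raise ValueError("each group needs at least one training vector")
        if self.recurrent_vectors.shape[1] != i or self.nonrecurrent_vectors.shape[1] != i:
            raise ValueError("training vectors do not match signature length")

    @classmethod
    def from_expression(
        cls,
        expr: ExpressionMatrix,
        labels: Mapping[str, bool],
        signature_gene_ids: Sequence[str],
    ) -> "TrainingReference":
        rec, nonrec = [], []
        for s in expr.sample_ids:
            v = expr.sample_vector(s, signature_gene_ids)
            (rec if labels[s] else nonrec).append(v)
        return cls(list(signature_gene_ids), np.array(rec), np.array(nonrec))


@dataclass
class ScorePair:
    """(recurrence score, non-recurrence score) for one query sample.

    The margin (non-recurrence minus recurrence score) is the quantity the
    ROC modifier shifts; ``predicted`` is the base-rule label.
    """

    sample_id: str
    recurrence_score: float
    nonrecurrence_score: float

    def __post_init__(self) -> None:
        for v in (self.recurrence_score, self.nonrecurrence_score):
            if not np.isfinite(v) or v < 0:
                raise ValueError("scores must be finite and non-negative")

    @property
    def margin(self) -> float:
        return self.nonrecurrence_score - self.recurrence_score

    @property
    def predicted(self) -> str:
        return predict(self)


def _check_query(ref: TrainingReference, x) -> np.ndarray:
    x = np.asarray(x, float).ravel()
    if x.size != len(ref.signature_gene_ids):
        raise ValueError(
            f"query has {x.size} genes, signature has {len(ref.signature_gene_ids)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("query vector must be finite")
    return x


def score_distance(
    ref: TrainingReference, x, sample_id: str = "", normalization: str = "mean"
) -> ScorePair:
    """Summed (or mean) Euclidean distance to every member of each group."""
    x = _check_query(ref, x)
    if normalization not in ("mean", "raw_sum"):
        raise ValueError(f"unknown distance normalization {normalization!r}")
    d_rec = np.linalg.norm(ref.recurrent_vectors - x, axis=1)
    d_non = np.linalg.norm(ref.nonrecurrent_vectors - x, axis=1)
    if normalization == "mean":
        return ScorePair(sample_id, float(d_rec.mean()), float(d_non.mean()))
    return ScorePair(sample_id, float(d_rec.sum()), float(d_non.sum()))


def score_centroid(ref: TrainingReference, x, sample_id: str = "") -> ScorePair:
    """Euclidean distance to each group's arithmetic centroid."""
    x = _check_query(ref, x)
    c_rec = ref.recurrent_vectors.mean(axis=0)
    c_non = ref.nonrecurrent_vectors.mean(axis=0)
    return ScorePair(
        sample_id,
        float(np.linalg.norm(x - c_rec)),
        float(np.linalg.norm(x - c_non)),
    )


def score_nearest_neighbor(ref: TrainingReference, x, sample_id: str = "") -> ScorePair:
    """Euclidean distance to the closest member of each group."""
    x = _check_query(ref, x)
    d_rec = np.linalg.norm(ref.recurrent_vectors - x, axis=1)
    d_non = np.linalg.norm(ref.nonrecurrent_vectors - x, axis=1)
    return ScorePair(sample_id, float(d_rec.min()), float(d_non.min()))


ALGORITHMS = {
    "centroid": score_centroid,
    "distance": score_distance,
    "nearest_neighbor": score_nearest_neighbor,
}


def score_with(algorithm: str, ref: TrainingReference, x, sample_id: str = "",
               distance_normalization: str = "mean") -> ScorePair:
    """Dispatch on algorithm name ({centroid, distance, nearest_neighbor})."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if algorithm == "distance":
        return score_distance(ref, x, sample_id, normalization=distance_normalization)
    return ALGORITHMS[algorithm](ref, x, sample_id)


def predict(score_pair: ScorePair, modifier: float = 0.0) -> str:
    """Recurrent iff margin + modifier >= 0 (ties favor recurrence).

    With modifier 0 this is the lower-score rule; a large positive
    modifier calls everything recurrent and a large negative one nothing.
    """
    if not np.isfinite(modifier):
        raise ValueError("modifier must be finite")
    return RECURRENT if score_pair.margin + modifier >= 0 else NONRECURRENT
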