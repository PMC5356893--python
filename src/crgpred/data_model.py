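"""Core domain types and tabular I/O for the recurrence-prediction pipeline.

The pipeline starts from called qPCR cycle-threshold (Ct) values on a gene
panel (rows = genes, columns = samples, the TLDA export convention) plus a
per-patient clinical annotation table (TNM staging, surgical margins, Gleason
patterns, biochemical-recurrence outcome and follow-up time).  Non-detects —
reactions that never crossed threshold — are carried as an explicit boolean
mask, never as a magic Ct value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RECURRENT",
    "NONRECURRENT",
    "T_STAGES",
    "N_STAGES",
    "M_STAGES",
    "CtMatrix",
    "ExpressionMatrix",
    "ClinicalRecord",
    "CohortSplit",
    "Prediction",
    "stage_at_or_below",
    "weeks_to_months",
    "read_ct_table",
    "write_ct_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_predictions",
    "write_predictions",
]

#: Canonical prediction labels (positive class = recurrent).
RECURRENT = "recurrent"
NONRECURRENT = "nonrecurrent"

#: Total order on the clinical primary-tumor axis.
T_STAGES = ("T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4")
N_STAGES = ("N0", "N1")
M_STAGES = ("M0", "M1")

_T_INDEX = {s.lower(): i for i, s in enumerate(T_STAGES)}
_N_INDEX = {s.lower(): i for i, s in enumerate(N_STAGES)}
_M_INDEX = {s.lower(): i for i, s in enumerate(M_STAGES)}


def _canonical_stage(token: str, index: dict, axis: str) -> str:
    key = str(token).strip().lower()
    if key not in index:
        raise ValueError(f"unknown {axis} stage token: {token!r}")
    if axis == "T":
        return T_STAGES[index[key]]
    if axis == "N":
        return N_STAGES[index[key]]
    return M_STAGES[index[key]]


def weeks_to_months(weeks: float) -> float:
    """Convert a follow-up time in weeks to months (12 months per 52 weeks)."""
    return weeks * 12.0 / 52.0


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CtMatrix:
    """Raw qPCR cycle-threshold values with a non-detect mask.

    ``ct`` is genes x samples; cells where ``detected`` is False hold NaN
    (the in-memory sentinel) and represent reactions with no amplification.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    ct: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.ct.shape != shape or self.detected.shape != shape:
            raise ValueError(
                f"ct/detected shape {self.ct.shape}/{self.detected.shape} "
                f"does not match gene_ids x sample_ids {shape}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        vals = self.ct[self.detected]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
            raise ValueError("detected Ct values must be finite and > 0")
        # non-detect cells carry NaN, never a plausible cycle value
        self.ct = self.ct.copy()
        self.ct[~self.detected] = np.nan

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in panel") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "CtMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CtMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            ct=self.ct[:, idx],
            detected=self.detected[:, idx],
        )

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            list(self.gene_ids), list(self.sample_ids),
            self.ct.copy(), self.detected.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Reference-normalized log2 expression (Delta-Ct relative to reference).

    ``expr[g, s] = ct[reference, s] - ct[g, s]``: higher means more
    expressed.  The reference gene itself never appears (its normalized
    value is identically zero).  ``detected`` is all-True once non-detects
    have been imputed or substituted; otherwise NaN marks flagged cells.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    expr: np.ndarray
    provenance: str  # {"imputed", "unimputed"}
    detected: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.expr.shape != shape:
            raise ValueError("expr shape does not match gene_ids x sample_ids")
        if self.detected is None:
            self.detected = np.ones(shape, dtype=bool)
        else:
            self.detected = np.asarray(self.detected, dtype=bool)
            if self.detected.shape != shape:
                raise ValueError("detected shape mismatch")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.provenance not in ("imputed", "unimputed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.all(np.isfinite(self.expr[self.detected])):
            raise ValueError("detected expression values must be finite")

    @property
    def is_complete(self) -> bool:
        return bool(np.all(self.detected))

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def sample_vector(self, sample_id: str, gene_ids: Sequence[str]) -> np.ndarray:
        """Expression of ``gene_ids`` (in order) for one sample."""
        s = self.sample_ids.index(sample_id)
        rows = [self.gene_index(g) for g in gene_ids]
        return self.expr[rows, s]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            expr=self.expr[:, idx],
            provenance=self.provenance,
            detected=self.detected[:, idx],
        )


def _parse_bool(token, what: str) -> bool:
    key = str(token).strip().lower()
    if key in ("1", "true", "yes", "y", "pos", "positive"):
        return True
    if key in ("0", "false", "no", "n", "neg", "negative"):
        return False
    raise ValueError(f"cannot parse {what} value {token!r}")


@dataclass
class ClinicalRecord:
    """Per-patient staging, margins, Gleason patterns, outcome and follow-up.

    ``recurred`` is None for blinded samples; ``time_to_event`` is months to
    biochemical recurrence when recurred, censoring time otherwise.
    """

    sample_id: str
    t_stage: str
    n_stage: str
    m_stage: str
    margins_negative: bool
    gleason_primary: int
    gleason_secondary: int
    recurred: Optional[bool]
    time_to_event: float
    psa: Optional[float] = None

    def __post_init__(self) -> None:
        self.t_stage = _canonical_stage(self.t_stage, _T_INDEX, "T")
        self.n_stage = _canonical_stage(self.n_stage, _N_INDEX, "N")
        self.m_stage = _canonical_stage(self.m_stage, _M_INDEX, "M")
        for pat in (self.gleason_primary, self.gleason_secondary):
            if not (1 <= int(pat) <= 5):
                raise ValueError(f"Gleason pattern {pat} outside 1-5")
        self.gleason_primary = int(self.gleason_primary)
        self.gleason_secondary = int(self.gleason_secondary)
        if not (self.time_to_event > 0):
            raise ValueError("time_to_event must be > 0")
        if self.psa is not None and self.psa < 0:
            raise ValueError("psa must be >= 0")

    @property
    def gleason_sum(self) -> int:
        return self.gleason_primary + self.gleason_secondary


def stage_at_or_below(rec: ClinicalRecord, t_max: str = "T2b") -> bool:
    """Component-wise organ-confined test: t_stage <= ``t_max``, N0 and M0.

    "T2bN0M0 or below" compares each TNM axis separately, not
    lexicographically.
    """
    return (
        _T_INDEX[rec.t_stage.lower()] <= _T_INDEX[t_max.lower()]
        and rec.n_stage == "N0"
        and rec.m_stage == "M0"
    )


@dataclass
class CohortSplit:
    """Disjoint training / validation sample-id sets."""

    training_ids: list[str]
    validation_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"training/validation overlap: {sorted(overlap)}")


@dataclass
class Prediction:
    """One per-sample prediction row as written to the predictions table."""

    sample_id: str
    predicted: str
    recurrence_score: Optional[float]
    nonrecurrence_score: Optional[float]
    strategy: str


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_ct_table(path, nondetect_token: str = "ND") -> CtMatrix:
    """Read a delimited Ct table (first column = gene symbol, header = samples).

    Cells are numeric Ct values or ``nondetect_token``; the delimiter is
    inferred from the extension (.csv comma, otherwise tab).
    """
    sep = _sep_for(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    # pandas mangles duplicate column names, so validate the raw header
    _check_unique([c.strip() for c in header[1:]], "sample")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [c.strip() for c in header[1:]]
    _check_unique(gene_ids, "gene")
    ct = np.empty(df.shape, dtype=float)
    detected = np.ones(df.shape, dtype=bool)
    token = nondetect_token.strip().lower()
    for i, g in enumerate(gene_ids):
        for j, s in enumerate(sample_ids):
            cell = str(df.iat[i, j]).strip()
            if cell.lower() == token:
                ct[i, j] = np.nan
                detected[i, j] = False
                continue
            try:
                ct[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {g!r}, sample {s!r}"
                ) from None
    return CtMatrix(gene_ids, sample_ids, ct, detected)


def write_ct_table(path, ct: CtMatrix, nondetect_token: str = "ND") -> None:
    """Write a CtMatrix so that :func:`read_ct_table` round-trips bit-exactly."""
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene" + sep + sep.join(ct.sample_ids) + "\n")
        for i, g in enumerate(ct.gene_ids):
            cells = [
                repr(float(ct.ct[i, j])) if ct.detected[i, j] else nondetect_token
                for j in range(ct.n_samples)
            ]
            fh.write(g + sep + sep.join(cells) + "\n")


_CLINICAL_COLUMNS = [
    "sample_id", "t_stage", "n_stage", "m_stage", "margins",
    "gleason_primary", "gleason_secondary", "recurred", "time_months", "psa",
]


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read a clinical annotation table into :class:`ClinicalRecord` rows.

    Stage strings are parsed case-insensitively; the ``recurred`` column
    accepts {0, 1, yes, no, NA} with NA meaning a blinded outcome.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in _CLINICAL_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        rec_token = str(row["recurred"]).strip().lower()
        recurred: Optional[bool]
        if rec_token in ("na", "nan", ""):
            recurred = None
        else:
            recurred = _parse_bool(rec_token, "recurred")
        psa = None
        if "psa" in df.columns:
            psa_token = str(row.get("psa", "")).strip().lower()
            if psa_token not in ("", "na", "nan"):
                psa = float(psa_token)
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                t_stage=row["t_stage"],
                n_stage=row["n_stage"],
                m_stage=row["m_stage"],
                margins_negative=not _parse_bool(row["margins"], "margins"),
                gleason_primary=int(row["gleason_primary"]),
                gleason_secondary=int(row["gleason_secondary"]),
                recurred=recurred,
                time_to_event=float(row["time_months"]),
                psa=psa,
            )
        )
    _check_unique([r.sample_id for r in records], "sample")
    return records


def write_clinical_table(path, records: Iterable[ClinicalRecord]) -> None:
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(_CLINICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(sep.join([
                r.sample_id, r.t_stage, r.n_stage, r.m_stage,
                "neg" if r.margins_negative else "pos",
                str(r.gleason_primary), str(r.gleason_secondary),
                "NA" if r.recurred is None else ("1" if r.recurred else "0"),
                repr(float(r.time_to_event)),
                "NA" if r.psa is None else repr(float(r.psa)),
            ]) + "\n")


_PREDICTION_COLUMNS = [
    "sample_id", "predicted", "recurrence_score", "nonrecurrence_score",
    "strategy",
]


def write_predictions(path, predictions: Iterable[Prediction]) -> None:
    """Write per-sample predictions as a TSV with a deterministic column order."""
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(_PREDICTION_COLUMNS) + "\n")
        for p in predictions:
            fh.write(sep.join([
                p.sample_id,
                p.predicted,
                "NA" if p.recurrence_score is None else repr(float(p.recurrence_score)),
                "NA" if p.nonrecurrence_score is None else repr(float(p.nonrecurrence_score)),
                p.strategy,
            ]) + "\n")


def read_predictions(path) -> list[Prediction]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    out = []
    for _, row in df.iterrows():
        def _score(tok):
            tok = str(tok).strip()
            return None if tok.lower() in ("na", "nan") else float(tok)
        out.append(Prediction(
            sample_id=str(row["sample_id"]),
            predicted=str(row["predicted"]),
            recurrence_score=_score(row["recurrence_score"]),
            nonrecurrence_score=_score(row["nonrecurrence_score"]),
            strategy=str(row["strategy"]),
        ))
    return out
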