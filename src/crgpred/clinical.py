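"""Clinical decision rules and the hybrid prediction strategies.

Eight strategies combine three sources of evidence: the expression-based
classifier ("CRG"), Gleason-score cutoffs, and an organ-confined surgical
rule (tumors staged T2bN0M0 or below with negative margins are considered
cured by surgery and called non-recurrent).

Strategies: 1 CRG only; 2 Gleason >= 7 recurrent; 3 Gleason 4+3 or above
recurrent; 4 surgical rule, recurrent otherwise; 5 surgical rule, CRG on
the rest; 6 Gleason 9-10 recurrent / 2-6 non-recurrent, CRG in between;
7 surgical rule then strategy 2; 8 surgical rule then strategy 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .data_model import ClinicalRecord, NONRECURRENT, RECURRENT, stage_at_or_below

__all__ = [
    "StrategyResult",
    "STRATEGY_NAMES",
    "surgical_rule",
    "gleason_rule",
    "crg_gleason_rule",
    "run_strategy",
]

STRATEGY_NAMES = {
    1: "crg",
    2: "gleason1",
    3: "gleason2",
    4: "surgery",
    5: "crg+surgery",
    6: "crg+gleason",
    7: "gleason1+surgery",
    8: "gleason2+surgery",
}

#: provenance tags
CLINICAL_RULE = "clinical_rule"
CRG_ALGORITHM = "crg_algorithm"
GLEASON_RULE = "gleason_rule"


@dataclass
class StrategyResult:
    strategy: str
    labels: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)


def surgical_rule(rec: ClinicalRecord, require_negative_margins: bool = True) -> Optional[str]:
    """Organ-confined rule: non-recurrent if staged T2bN0M0 or below.

    Margins must additionally be negative unless
    ``require_negative_margins`` is False.  Returns ``"nonrecurrent"`` or
    None (escalate: the caller decides what happens to samples the rule
    cannot clear).  "< T2c" and "<= T2b" are the same cut on the T axis.
    """
    if stage_at_or_below(rec, "T2b") and (rec.margins_negative or not require_negative_margins):
        return NONRECURRENT
    return None


def gleason_rule(rec: ClinicalRecord, variant: str = "g1") -> str:
    """Gleason cutoffs: g1 — recurrent iff sum >= 7; g2 — recurrent iff
    sum > 7 or sum == 7 with primary pattern 4 (4+3 but not 3+4)."""
    s = rec.gleason_sum
    if variant == "g1":
        return RECURRENT if s >= 7 else NONRECURRENT
    if variant == "g2":
        if s > 7 or (s == 7 and rec.gleason_primary == 4):
            return RECURRENT
        return NONRECURRENT
    raise ValueError(f"unknown Gleason variant {variant!r}")


def crg_gleason_rule(rec: ClinicalRecord, crg_prediction: str) -> str:
    """Gleason extremes decide; the 7-8 band defers to the CRG prediction."""
    s = rec.gleason_sum
    if s >= 9:
        return RECURRENT
    if s <= 6:
        return NONRECURRENT
    return crg_prediction


def run_strategy(
    strategy_id: int,
    cohort: Sequence[ClinicalRecord],
    crg_predictions: Optional[Mapping[str, str]] = None,
    require_negative_margins: bool = True,
) -> StrategyResult:
    """Apply one of the eight hybrid strategies to a cohort.

    ``crg_predictions`` maps sample id to the expression classifier's
    label; it is required for strategies 1, 5 and 6 (and only consulted
    for the samples those strategies route to the classifier).
    """
    if strategy_id not in STRATEGY_NAMES:
        raise ValueError(f"unknown strategy {strategy_id}")
    name = STRATEGY_NAMES[strategy_id]
    needs_crg = strategy_id in (1, 5, 6)
    if needs_crg and crg_predictions is None:
        raise ValueError(f"strategy {strategy_id} ({name}) needs CRG predictions")

    out = StrategyResult(strategy=name)

    def crg_of(rec: ClinicalRecord) -> str:
        try:
            return crg_predictions[rec.sample_id]  # type: ignore[index]
        except KeyError:
            raise ValueError(f"no CRG prediction for sample {rec.sample_id!r}") from None

    for rec in cohort:
        sid = rec.sample_id
        if strategy_id == 1:
            out.labels[sid] = crg_of(rec)
            out.provenance[sid] = CRG_ALGORITHM
        elif strategy_id in (2, 3):
            out.labels[sid] = gleason_rule(rec, "g1" if strategy_id == 2 else "g2")
            out.provenance[sid] = GLEASON_RULE
        elif strategy_id == 4:
            surg = surgical_rule(rec, require_negative_margins)
            out.labels[sid] = surg if surg is not None else RECURRENT
            out.provenance[sid] = CLINICAL_RULE
        elif strategy_id == 5:
            surg = surgical_rule(rec, require_negative_margins)
            if surg is not None:
                out.labels[sid] = surg
                out.provenance[sid] = CLINICAL_RULE
            else:
                out.labels[sid] = crg_of(rec)
                out.provenance[sid] = CRG_ALGORITHM
        elif strategy_id == 6:
            s = rec.gleason_sum
            if 7 <= s <= 8:
                out.labels[sid] = crg_of(rec)
                out.provenance[sid] = CRG_ALGORITHM
            else:
                out.labels[sid] = crg_gleason_rule(rec, NONRECURRENT)
                out.provenance[sid] = GLEASON_RULE
        else:  # 7, 8
            surg = surgical_rule(rec, require_negative_margins)
            if surg is not None:
                out.labels[sid] = surg
                out.provenance[sid] = CLINICAL_RULE
            else:
                out.labels[sid] = gleason_rule(rec, "g1" if strategy_id == 7 else "g2")
                out.provenance[sid] = GLEASON_RULE
    return out
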