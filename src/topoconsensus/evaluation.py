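"""Benchmark criteria for topology predictions.

A prediction is *correct* when it has the same number of membrane helices
as the reference, each predicted helix overlaps its in-order counterpart by
at least ``min_overlap`` residues (default 5), the membrane orientation of
the N- and C-termini matches (read past any signal peptide; only checked
when the reference spans the membrane), and signal-peptide presence agrees.
For references without membrane segments this reduces to the usual
proteome-scanning criteria: a globular protein must receive neither
helices nor a signal peptide, a secreted protein exactly a signal peptide.

Incorrect predictions are sorted into an error taxonomy:

``WRONG_TOPOLOGY``
    right protein class, wrong topology (extra/missing/misplaced helices,
    inverted orientation);
``TM_SP_CONFUSION``
    an N-terminal membrane helix mistaken for a signal peptide or vice
    versa (the classic cross-prediction error);
``TM_NONTM_CONFUSION``
    membrane-helix presence itself disagrees (beyond the SP case);
``SP_NONTM_CONFUSION``
    signal-peptide presence disagrees with no membrane involvement.

Aggregation produces per-class accuracies, a 4x4 reference-vs-predicted
class confusion matrix (row-normalized percentages) and error-kind counts
per reference class.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    Segment,
    TopologyClass,
    TopologyString,
    classify,
    segments_from_labels,
)

CLASS_ORDER = (
    TopologyClass.TM,
    TopologyClass.SP_TM,
    TopologyClass.SP_ONLY,
    TopologyClass.GLOBULAR,
)


class ErrorKind(Enum):
    CORRECT = "Correct"
    WRONG_TOPOLOGY = "Wrong topology"
    TM_SP_CONFUSION = "TM <-> SP"
    TM_NONTM_CONFUSION = "TM <-> non-TM"
    SP_NONTM_CONFUSION = "SP <-> non-TM"


KIND_ORDER = (
    ErrorKind.CORRECT,
    ErrorKind.WRONG_TOPOLOGY,
    ErrorKind.TM_SP_CONFUSION,
    ErrorKind.TM_NONTM_CONFUSION,
    ErrorKind.SP_NONTM_CONFUSION,
)


@dataclass(frozen=True)
class EvalConfig:
    """Correctness thresholds.

    ``min_overlap``: minimum shared residues between paired helices.
    ``require_termini``: demand matching N-/C-terminal membrane sides.
    ``sp_territory``: N-terminal stretch (residues) within which a
    membrane-helix/signal-peptide disagreement counts as cross-prediction
    rather than a helix-presence error; 70 matches the maximum admitted
    signal-peptide length.
    """

    min_overlap: int = 5
    require_termini: bool = True
    sp_territory: int = 70

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.sp_territory < 0:
            raise ValueError("sp_territory must be >= 0")


DEFAULT_EVAL = EvalConfig()


@dataclass(frozen=True)
class EvalOutcome:
    protein_id: str
    ref_class: TopologyClass
    pred_class: TopologyClass
    correct: bool
    error_kind: ErrorKind


def _m_segments(topo: TopologyString) -> List[Segment]:
    return [s for s in segments_from_labels(topo) if s.label == "M"]


def _terminal_sides(topo: TopologyString) -> Tuple[Optional[str], Optional[str]]:
    """First and last membrane-side label (i/o), skipping SP and helices."""
    first = next((c for c in topo.labels if c in "io"), None)
    last = next((c for c in reversed(topo.labels) if c in "io"), None)
    return first, last


def topology_correct(
    ref: TopologyString, pred: TopologyString, cfg: EvalConfig = DEFAULT_EVAL
) -> bool:
    """Per-protein correctness under the benchmark criterion (see module doc)."""
    if len(ref) != len(pred):
        raise ValueError(
            f"length mismatch for {ref.protein_id!r}: reference {len(ref)}, "
            f"prediction {len(pred)}"
        )
    if ("S" in ref.labels) != ("S" in pred.labels):
        return False
    ref_m = _m_segments(ref)
    pred_m = _m_segments(pred)
    if len(ref_m) != len(pred_m):
        return False
    for r, p in zip(ref_m, pred_m):
        if r.overlap(p) < cfg.min_overlap:
            return False
    if cfg.require_termini and ref_m:
        if _terminal_sides(ref) != _terminal_sides(pred):
            return False
    return True


def judge(
    ref: TopologyString, pred: TopologyString, cfg: EvalConfig = DEFAULT_EVAL
) -> EvalOutcome:
    """Correctness plus error-kind diagnosis for one protein.

    Rule order (first match wins): correct; SP<->helix cross-prediction
    when exactly one side has an S run and the other has a membrane helix
    inside the N-terminal ``sp_territory``; helix-presence disagreement;
    signal-peptide-presence disagreement; otherwise wrong topology.
    """
    if len(ref) != len(pred):
        raise ValueError(
            f"length mismatch for {ref.protein_id!r}: reference {len(ref)}, "
            f"prediction {len(pred)}"
        )
    rc, pc = classify(ref), classify(pred)
    if topology_correct(ref, pred, cfg):
        kind = ErrorKind.CORRECT
    else:
        ref_s = "S" in ref.labels
        pred_s = "S" in pred.labels
        ref_m = _m_segments(ref)
        pred_m = _m_segments(pred)
        kind = ErrorKind.WRONG_TOPOLOGY
        if ref_s != pred_s:
            no_sp_side_m = pred_m if ref_s else ref_m
            if any(seg.start < cfg.sp_territory for seg in no_sp_side_m):
                kind = ErrorKind.TM_SP_CONFUSION
            elif bool(ref_m) != bool(pred_m):
                kind = ErrorKind.TM_NONTM_CONFUSION
            else:
                kind = ErrorKind.SP_NONTM_CONFUSION
        elif bool(ref_m) != bool(pred_m):
            kind = ErrorKind.TM_NONTM_CONFUSION
    return EvalOutcome(
        protein_id=ref.protein_id,
        ref_class=rc,
        pred_class=pc,
        correct=kind is ErrorKind.CORRECT,
        error_kind=kind,
    )


@dataclass(frozen=True, eq=False)
class BenchmarkReport:
    """Aggregated benchmark over a matched reference/prediction set."""

    outcomes: Tuple[EvalOutcome, ...]
    class_accuracy: Dict[TopologyClass, Tuple[int, int]]  # class -> (correct, total)
    confusion_counts: pd.DataFrame   # rows: reference class, cols: predicted
    error_kind_counts: pd.DataFrame  # rows: reference class, cols: error kind

    @property
    def n_proteins(self) -> int:
        return len(self.outcomes)

    @property
    def overall_accuracy(self) -> float:
        return sum(o.correct for o in self.outcomes) / self.n_proteins

    def accuracy(self, cls: TopologyClass) -> float:
        correct, total = self.class_accuracy.get(cls, (0, 0))
        return correct / total if total else float("nan")

    @property
    def confusion_percent(self) -> pd.DataFrame:
        """Row-normalized confusion matrix in percent (rows with proteins)."""
        totals = self.confusion_counts.sum(axis=1)
        pct = self.confusion_counts.div(totals.where(totals > 0), axis=0) * 100.0
        return pct.fillna(0.0)

    def to_text(self) -> str:
        lines = [f"Benchmark over {self.n_proteins} proteins", ""]
        lines.append("Correct-prediction fraction per reference class:")
        for cls in CLASS_ORDER:
            correct, total = self.class_accuracy.get(cls, (0, 0))
            if total:
                lines.append(
                    f"  {cls.value:<10s} {100.0 * correct / total:5.1f}%  "
                    f"({correct}/{total})"
                )
        lines.append(f"  {'Overall':<10s} {100.0 * self.overall_accuracy:5.1f}%  "
                     f"({sum(o.correct for o in self.outcomes)}/{self.n_proteins})")
        lines.append("")
        lines.append("Class confusion (rows: reference, cols: predicted; row %):")
        lines.append(self.confusion_percent.round(1).to_string())
        lines.append("")
        lines.append("Error kinds per reference class (counts):")
        lines.append(self.error_kind_counts.to_string())
        lines.append("")
        return "\n".join(lines)


def benchmark(
    refs: Mapping[str, TopologyString],
    preds: Mapping[str, TopologyString],
    cfg: EvalConfig = DEFAULT_EVAL,
) -> BenchmarkReport:
    """Judge every protein and aggregate (matched id sets required)."""
    if not refs:
        raise ValueError("empty reference set")
    missing = sorted(set(refs) - set(preds))
    extra = sorted(set(preds) - set(refs))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing predictions for: {', '.join(missing)}")
        if extra:
            parts.append(f"predictions without reference: {', '.join(extra)}")
        raise ValueError("; ".join(parts))

    outcomes = tuple(judge(refs[pid], preds[pid], cfg) for pid in sorted(refs))

    class_names = [c.value for c in CLASS_ORDER]
    confusion = pd.DataFrame(0, index=class_names, columns=class_names, dtype=int)
    kinds = pd.DataFrame(
        0, index=class_names, columns=[k.value for k in KIND_ORDER], dtype=int
    )
    class_acc: Dict[TopologyClass, Tuple[int, int]] = {}
    for o in outcomes:
        confusion.loc[o.ref_class.value, o.pred_class.value] += 1
        kinds.loc[o.ref_class.value, o.error_kind.value] += 1
        c, t = class_acc.get(o.ref_class, (0, 0))
        class_acc[o.ref_class] = (c + int(o.correct), t + 1)

    return BenchmarkReport(
        outcomes=outcomes,
        class_accuracy=class_acc,
        confusion_counts=confusion,
        error_kind_counts=kinds,
    )
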