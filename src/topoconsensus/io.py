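"""On-disk formats: FASTA, topology tables, reports.

Topology predictions and reference annotations travel in one TSV dialect:
three tab-separated columns ``protein_id``, ``method`` (or annotation
source), ``topology string``; ``#`` starts a comment.  The report writer
emits a plain-text analogue of the usual consensus-server output: the
consensus string with the per-method strings aligned beneath it, a 1-based
inclusive segment table, the protein class, the path score and the
per-residue agreement track.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .consensus import ConsensusResult
from .core import (
    VALID_LABELS,
    ProteinRecord,
    TopologyString,
    classify,
    segments_from_labels,
)
from .dg import DgTrack

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> List[ProteinRecord]:
    """Read protein records; ids must be unique, sequences are uppercased.

    A single trailing ``*`` (stop) is stripped with a warning; any
    character outside the 20 standard codes plus X/B/Z is an error.
    """
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            logger.warning("%s: stripping trailing '*' from %r", path, rec.id)
            seq = seq[:-1]
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[k : k + width] + "\n")


@dataclass(frozen=True)
class PredictionRow:
    protein_id: str
    method: str
    topology: TopologyString


@dataclass(frozen=True, eq=False)
class PredictionTable:
    """Per-method topology strings, in file order."""

    rows: tuple

    def protein_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.protein_id, None)
        return list(seen)

    def predictions_for(self, protein_id: str) -> List[TopologyString]:
        return [r.topology for r in self.rows if r.protein_id == protein_id]

    def methods_for(self, protein_id: str) -> List[str]:
        return [r.method for r in self.rows if r.protein_id == protein_id]

    def __len__(self) -> int:
        return len(self.rows)


def _parse_topology(
    labels: str, protein_id: str, method: str, lineno: int, path: PathLike
) -> TopologyString:
    for k, c in enumerate(labels):
        if c not in VALID_LABELS:
            raise ValueError(
                f"{path}:{lineno}: unknown label {c!r} at position {k} "
                f"(protein {protein_id!r}, method {method!r})"
            )
    return TopologyString(protein_id, labels)


def read_predictions(
    path: PathLike,
    proteins: Optional[Mapping[str, ProteinRecord]] = None,
) -> PredictionTable:
    """Read a 3-column topology TSV; length-check against ``proteins`` if given."""
    rows: List[PredictionRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            pid, method, labels = parts
            topo = _parse_topology(labels, pid, method, lineno, path)
            if proteins is not None:
                if pid not in proteins:
                    raise ValueError(f"{path}:{lineno}: unknown protein id {pid!r}")
                expected = proteins[pid].length
                if len(topo) != expected:
                    raise ValueError(
                        f"{path}:{lineno}: topology length {len(topo)} != sequence "
                        f"length {expected} (protein {pid!r}, method {method!r})"
                    )
            rows.append(PredictionRow(pid, method, topo))
    if not rows:
        raise ValueError(f"{path}: no prediction rows found")
    return PredictionTable(rows=tuple(rows))


def write_predictions(table: PredictionTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tmethod\ttopology\n")
        for row in table.rows:
            fh.write(f"{row.protein_id}\t{row.method}\t{row.topology.labels}\n")


def read_reference(
    path: PathLike,
    proteins: Optional[Mapping[str, ProteinRecord]] = None,
) -> Dict[str, TopologyString]:
    """Read a topology table expected to hold exactly one row per protein."""
    table = read_predictions(path, proteins)
    out: Dict[str, TopologyString] = {}
    for row in table.rows:
        if row.protein_id in out:
            raise ValueError(
                f"{path}: multiple topology rows for protein {row.protein_id!r}"
            )
        out[row.protein_id] = row.topology
    return out


def _agreement_digits(agreement: Sequence[float]) -> str:
    """Render per-residue agreement as digits 0..9 (9 = unanimous)."""
    return "".join(str(min(9, int(round(a * 10)))) for a in agreement)


def write_report(
    results: Mapping[str, ConsensusResult],
    path: PathLike,
    predictions: Optional[PredictionTable] = None,
    dg_tracks: Optional[Mapping[str, DgTrack]] = None,
) -> None:
    """Write one text block per protein; byte-stable across reruns."""
    if not results:
        raise ValueError("no consensus results to report")
    with open(path, "w") as fh:
        for pid, res in results.items():
            topo = res.topology
            fh.write(f">{pid} length={len(topo)} class={classify(topo).value} "
                     f"score={res.log_geometric_mean_score:.6f}\n")
            fh.write(f"{'consensus':<12s} {topo.labels}\n")
            if predictions is not None:
                for method, pred in zip(
                    predictions.methods_for(pid), predictions.predictions_for(pid)
                ):
                    fh.write(f"{method:<12s} {pred.labels}\n")
            fh.write(f"{'agreement':<12s} {_agreement_digits(res.per_residue_agreement)}\n")
            fh.write("segments (1-based, inclusive):\n")
            for seg in segments_from_labels(topo):
                fh.write(f"  {seg.label}  {seg.start + 1}-{seg.end}\n")
            if dg_tracks is not None and pid in dg_tracks and len(dg_tracks[pid]):
                track = dg_tracks[pid]
                vals = track.values
                k = int(vals.argmin())
                fh.write(
                    f"dG: {len(track)} windows (w={track.window}), "
                    f"min {vals[k]:.2f} kcal/mol at position {int(track.centers[k]) + 1}\n"
                )
            fh.write("\n")
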