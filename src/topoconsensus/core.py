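"""Domain model for membrane-protein topology.

A topology assigns each residue one of four labels:

``S``
    cleavable N-terminal signal peptide,
``M``
    membrane-spanning (transmembrane) helix,
``i``
    inside, i.e. cytoplasmic, loop or terminus,
``o``
    outside, i.e. non-cytoplasmic, loop or terminus.

Raw per-method predictions are arbitrary label strings and may violate
biological constraints.  What a *plausible* topology looks like — the signal
peptide sits at the N-terminus and is followed by the outside face, loops on
the two membrane sides alternate across every helix, helices have a minimum
length — is encoded in :class:`GrammarConfig` and checked by
:func:`validate_topology`.  The consensus decoder
(:mod:`topoconsensus.consensus`) only ever emits grammar-valid topologies;
inputs are deliberately not required to be valid.

Coordinates are 0-based half-open throughout the library; user-facing
reports convert to 1-based inclusive positions.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, List, Sequence, Tuple, Union

#: The four admissible residue labels, in profile column order.
VALID_LABELS = "SMio"
_LABEL_SET = frozenset(VALID_LABELS)

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes accepted (flagged, never silently dropped) in sequences.
AMBIGUOUS_AA = "XBZ"


class ResidueLabel(str, Enum):
    """The four per-residue topology labels."""

    SIGNAL = "S"
    MEMBRANE = "M"
    INSIDE = "i"
    OUTSIDE = "o"


class TopologyClass(Enum):
    """Protein-level class induced by a topology string.

    ``TM``: membrane helices, no signal peptide; ``SP_TM``: signal peptide
    plus membrane helices; ``SP_ONLY``: signal peptide only (secreted);
    ``GLOBULAR``: neither.
    """

    TM = "TM"
    SP_TM = "SP+TM"
    SP_ONLY = "SP-only"
    GLOBULAR = "Globular"


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence.

    Ambiguity codes X/B/Z are accepted and exposed through
    :attr:`has_ambiguous`; any other character is rejected.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - set(AMINO_ACIDS) - set(AMBIGUOUS_AA))
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid sequence character(s) {''.join(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_AA for c in self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TopologyString:
    """Per-residue topology labels for one protein.

    May be grammar-invalid: raw predictor output is not guaranteed to obey
    the topology grammar.  Use :func:`validate_topology` to check.
    """

    protein_id: str
    labels: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.labels) - _LABEL_SET)
        if bad:
            raise ValueError(
                f"topology for {self.protein_id!r}: invalid label(s) {''.join(bad)!r} "
                f"(allowed: {VALID_LABELS})"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        return self.labels

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)


@dataclass(frozen=True)
class Segment:
    """A maximal run of one label, 0-based half-open ``[start, end)``."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in _LABEL_SET:
            raise ValueError(f"invalid segment label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Segment") -> int:
        """Number of shared residue positions with ``other`` (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GrammarConfig:
    """Constraints a plausible topology must satisfy.

    The defaults encode the standard biology of alpha-helical membrane
    proteins: one cleavable signal peptide at most, located at the
    N-terminus and followed by the outside face (post-translocation side of
    a cleaved SP); membrane sides alternating across each helix; helices no
    shorter than ~15 residues (the minimal membrane-spanning helix); SP
    length within [5, 70].  ``max_helix_len=None`` leaves helix length
    unbounded above.
    """

    min_helix_len: int = 15
    max_helix_len: Union[int, None] = None
    min_sp_len: int = 5
    max_sp_len: int = 70
    sp_must_start_at_nterm: bool = True
    post_sp_side: str = "o"
    allow_globular_paths: bool = True

    def __post_init__(self) -> None:
        if self.min_helix_len < 1:
            raise ValueError("min_helix_len must be >= 1")
        if self.max_helix_len is not None and self.max_helix_len < self.min_helix_len:
            raise ValueError("max_helix_len must be >= min_helix_len")
        if not (1 <= self.min_sp_len <= self.max_sp_len):
            raise ValueError("need 1 <= min_sp_len <= max_sp_len")
        if self.post_sp_side not in ("i", "o"):
            raise ValueError("post_sp_side must be 'i' or 'o'")


#: Default grammar used throughout when none is supplied.
DEFAULT_GRAMMAR = GrammarConfig()


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of :func:`validate_topology`: a verdict plus the violations."""

    valid: bool
    violations: Tuple[str, ...]

    def __bool__(self) -> bool:
        return self.valid


TopologyLike = Union[TopologyString, str]


def _labels_of(topo: TopologyLike) -> str:
    if isinstance(topo, TopologyString):
        return topo.labels
    labels = str(topo)
    bad = sorted(set(labels) - _LABEL_SET)
    if bad:
        raise ValueError(f"invalid label(s) {''.join(bad)!r} (allowed: {VALID_LABELS})")
    return labels


def segments_from_labels(topo: TopologyLike) -> List[Segment]:
    """Split a topology string into its maximal same-label runs, in order."""
    labels = _labels_of(topo)
    if not labels:
        raise ValueError("empty topology")
    segs: List[Segment] = []
    prev = labels[0]
    start = 0
    for k in range(1, len(labels)):
        c = labels[k]
        if c != prev:
            segs.append(Segment(prev, start, k))
            prev = c
            start = k
    segs.append(Segment(prev, start, len(labels)))
    return segs


def labels_from_segments(
    segs: Sequence[Segment], length: int, protein_id: str = ""
) -> TopologyString:
    """Inverse of :func:`segments_from_labels`.

    The segments must tile ``[0, length)`` exactly, in order, with no gaps
    or overlaps.
    """
    pos = 0
    parts: List[str] = []
    for seg in segs:
        if seg.start != pos:
            raise ValueError(
                f"segments do not tile sequence: expected start {pos}, got {seg.start}"
            )
        parts.append(seg.label * (seg.end - seg.start))
        pos = seg.end
    if pos != length:
        raise ValueError(
            f"segments do not tile sequence: cover [0, {pos}) but length is {length}"
        )
    return TopologyString(protein_id, "".join(parts))


def validate_topology(
    topo: TopologyLike, grammar: GrammarConfig = DEFAULT_GRAMMAR
) -> ValidationResult:
    """Check a topology against the grammar; returns verdict + violations.

    Rules (all must hold):

    * at most one ``S`` run; it must start at residue 0 (when
      ``sp_must_start_at_nterm``), have length within
      ``[min_sp_len, max_sp_len]``, and the residue following it, if any,
      must be ``post_sp_side`` (in particular never ``M``);
    * ``i`` and ``o`` runs are never adjacent (a membrane crossing is
      required to change sides);
    * every ``M`` run has length ``>= min_helix_len`` (and
      ``<= max_helix_len`` when bounded);
    * across an ``M`` run with loops on both flanks, the sides differ
      (``i -> M -> o`` or ``o -> M -> i``); an ``M`` run at either terminus
      has no constraint from the absent flank;
    * when ``allow_globular_paths`` is false, a topology with neither ``M``
      nor ``S`` is rejected.

    Violations are reported, never raised (except for an empty topology,
    which is a precondition failure).
    """
    segs = segments_from_labels(topo)
    v: List[str] = []

    s_runs = [s for s in segs if s.label == "S"]
    if len(s_runs) > 1:
        v.append(f"{len(s_runs)} signal-peptide runs (at most one allowed)")
    if s_runs:
        sp = s_runs[0]
        idx = segs.index(sp)
        if grammar.sp_must_start_at_nterm and sp.start != 0:
            v.append(f"signal peptide starts at {sp.start}, not at the N-terminus")
        if len(sp) < grammar.min_sp_len:
            v.append(
                f"signal peptide length {len(sp)} < minimum {grammar.min_sp_len}"
            )
        if len(sp) > grammar.max_sp_len:
            v.append(
                f"signal peptide length {len(sp)} > maximum {grammar.max_sp_len}"
            )
        if idx + 1 < len(segs):
            nxt = segs[idx + 1].label
            if nxt == "M":
                v.append("signal peptide directly followed by membrane helix")
            elif nxt != grammar.post_sp_side:
                v.append(
                    f"signal peptide followed by {nxt!r}, "
                    f"expected {grammar.post_sp_side!r}"
                )

    for a, b in zip(segs, segs[1:]):
        pair = {a.label, b.label}
        if pair == {"i", "o"}:
            v.append(f"'i' run adjacent to 'o' run at position {b.start}")
        if pair == {"M", "S"} and a.label == "M":
            # S-then-M is reported above; M-then-S means S not at N-terminus.
            v.append(f"membrane helix directly followed by signal peptide at {b.start}")

    for k, seg in enumerate(segs):
        if seg.label != "M":
            continue
        if len(seg) < grammar.min_helix_len:
            v.append(
                f"helix at {seg.start} shorter than minimum "
                f"({len(seg)} < {grammar.min_helix_len})"
            )
        if grammar.max_helix_len is not None and len(seg) > grammar.max_helix_len:
            v.append(
                f"helix at {seg.start} longer than maximum "
                f"({len(seg)} > {grammar.max_helix_len})"
            )
        left = segs[k - 1].label if k > 0 else None
        right = segs[k + 1].label if k + 1 < len(segs) else None
        if left in ("i", "o") and right in ("i", "o") and left == right:
            v.append(f"helix at {seg.start} does not switch sides ({left} -> {right})")

    if not grammar.allow_globular_paths and not s_runs:
        if all(seg.label in ("i", "o") for seg in segs):
            v.append("globular (no-helix, no-SP) topology not allowed")

    return ValidationResult(not v, tuple(v))


def classify(topo: TopologyLike) -> TopologyClass:
    """Protein-level class from label content (M and/or S presence)."""
    labels = _labels_of(topo)
    if not labels:
        raise ValueError("empty topology")
    has_m = "M" in labels
    has_s = "S" in labels
    if has_m:
        return TopologyClass.SP_TM if has_s else TopologyClass.TM
    return TopologyClass.SP_ONLY if has_s else TopologyClass.GLOBULAR
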