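"""Consensus topology decoding.

Per-method topology predictions are stacked into a *topology profile*: for
every residue, the fraction of methods voting for each of S, M, i and o.
The consensus is the grammar-valid label string maximizing the geometric
mean of the profile values along the path — equivalently the mean of logs —
found by a Viterbi-style dynamic program over a state machine that encodes
the topology grammar.  Each state emits exactly one label with score 1
(0 for the others) and all transitions are unweighted, so the profile alone
scores a path and the state machine alone constrains its shape; nothing is
trained.

Zero fractions would make every path through a disagreeing column score
-inf, so profile columns are smoothed with a small pseudocount and
renormalized before taking logs (see :class:`ConsensusConfig`).

Grammar length constraints (minimum helix / SP lengths) are carried by
chained sub-states; ties in the dynamic program are broken toward the
lowest-numbered state in the fixed order loops < M chains < S chain, which
prefers fewer membrane segments and makes output byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DEFAULT_GRAMMAR,
    VALID_LABELS,
    GrammarConfig,
    TopologyString,
    validate_topology,
)

LABEL_TO_COL = {c: k for k, c in enumerate(VALID_LABELS)}  # S,M,i,o -> 0..3


@dataclass(frozen=True, eq=False)
class TopologyProfile:
    """L x 4 per-residue voting fractions (columns ordered S, M, i, o)."""

    fractions: np.ndarray
    n_methods: int
    protein_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError("profile must be a non-empty (L, 4) array")
        if self.n_methods < 1:
            raise ValueError("n_methods must be >= 1")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("profile fractions must lie in [0, 1]")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must each sum to 1")

    @property
    def length(self) -> int:
        return int(self.fractions.shape[0])

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class ConsensusConfig:
    """Decoder settings.

    ``pseudocount`` is added to every fraction (with renormalization over
    the 4 labels) before logs are taken; it only matters where methods
    disagree completely and should stay well below ``1 / (2 * n_methods)``.
    """

    grammar: GrammarConfig = DEFAULT_GRAMMAR
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass(frozen=True, eq=False)
class ConsensusResult:
    """Decoded consensus topology.

    ``log_geometric_mean_score`` is ``(1/L) * sum_c log p~_c(label_c)`` on
    the smoothed profile; ``per_residue_agreement`` is the unsmoothed
    fraction of methods voting for the consensus label at each residue — a
    simple reliability track.
    """

    topology: TopologyString
    log_geometric_mean_score: float
    per_residue_agreement: np.ndarray


def build_profile(
    predictions: Sequence[TopologyString],
    length: Optional[int] = None,
    protein_id: str = "",
) -> TopologyProfile:
    """Stack per-method predictions into a topology profile.

    All predictions must share one length; fractions are exact rational
    counts over the methods supplied (methods are equally weighted, and a
    missing method simply is not in the list).
    """
    if not predictions:
        raise ValueError("no predictions given")
    L = length if length is not None else len(predictions[0])
    if L < 1:
        raise ValueError("profile length must be >= 1")
    counts = np.zeros((L, 4), dtype=float)
    rows = np.arange(L)
    for k, t in enumerate(predictions):
        if len(t) != L:
            raise ValueError(
                f"prediction #{k} ({t.protein_id!r}) has length {len(t)}, expected {L}"
            )
        idx = np.fromiter((LABEL_TO_COL[c] for c in t.labels), dtype=np.int64, count=L)
        counts[rows, idx] += 1.0
    n = len(predictions)
    pid = protein_id or predictions[0].protein_id
    return TopologyProfile(counts / n, n_methods=n, protein_id=pid)


def score_path(
    profile: TopologyProfile, topo: TopologyString, pseudocount: float = 1e-6
) -> float:
    """Mean log smoothed profile value along ``topo`` (log geometric mean)."""
    L = profile.length
    if len(topo) != L:
        raise ValueError(f"topology length {len(topo)} != profile length {L}")
    idx = np.fromiter((LABEL_TO_COL[c] for c in topo.labels), dtype=np.int64, count=L)
    vals = (profile.fractions[np.arange(L), idx] + pseudocount) / (1.0 + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        return float(np.mean(np.log(vals)))


# --------------------------------------------------------------------------
# Grammar state machine
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Machine:
    labels: Tuple[str, ...]              # emitted label per state
    preds: Tuple[Tuple[int, ...], ...]   # predecessor state indices, ascending
    start: Tuple[bool, ...]
    end: Tuple[bool, ...]


@lru_cache(maxsize=None)
def _build_machine(grammar: GrammarConfig) -> _Machine:
    """Expand the grammar into explicit states.

    State order (fixes the tie-break): inside loop(s), outside loop(s),
    i->o helix chain, o->i helix chain, S chain.  When globular paths are
    disallowed the two loops are each split into a pre-structure state
    (reachable only from the start, not a legal end) and a post-structure
    state, so that every accepted path crosses an M or S state.
    """
    split = not grammar.allow_globular_paths
    labels: List[str] = []
    names: List[str] = []

    def add(label: str, name: str) -> int:
        labels.append(label)
        names.append(name)
        return len(labels) - 1

    if split:
        i_pre = add("i", "i_pre")
        i_post = add("i", "i_post")
        o_pre = add("o", "o_pre")
        o_post = add("o", "o_post")
        loop_sources = {"i": (i_pre, i_post), "o": (o_pre, o_post)}
        loop_sink = {"i": i_post, "o": o_post}
    else:
        i_loop = add("i", "i")
        o_loop = add("o", "o")
        loop_sources = {"i": (i_loop,), "o": (o_loop,)}
        loop_sink = {"i": i_loop, "o": o_loop}

    K_m = grammar.max_helix_len if grammar.max_helix_len is not None else grammar.min_helix_len
    unbounded = grammar.max_helix_len is None
    helix_exit_ks = range(grammar.min_helix_len, K_m + 1)

    m_chain = {}
    for src, dst in (("i", "o"), ("o", "i")):
        m_chain[(src, dst)] = [add("M", f"M{src}{dst}_{k}") for k in range(1, K_m + 1)]

    K_s = grammar.max_sp_len
    s_chain = [add("S", f"S_{k}") for k in range(1, K_s + 1)]
    sp_exit_ks = range(grammar.min_sp_len, K_s + 1)

    n = len(labels)
    preds: List[List[int]] = [[] for _ in range(n)]
    start = [False] * n
    end = [False] * n

    # Loops: self-loop; receive helix exits on their side; receive SP exits
    # on the post-SP side.
    for side in ("i", "o"):
        for st in loop_sources[side]:
            preds[st].append(st)
        sink = loop_sink[side]
        other = "o" if side == "i" else "i"
        chain = m_chain[(other, side)]
        preds[sink].extend(chain[k - 1] for k in helix_exit_ks)
        if grammar.post_sp_side == side:
            preds[sink].extend(s_chain[k - 1] for k in sp_exit_ks)
    if split:
        start[loop_sources["i"][0]] = True
        start[loop_sources["o"][0]] = True
        end[loop_sink["i"]] = True
        end[loop_sink["o"]] = True
    else:
        for side in ("i", "o"):
            start[loop_sink[side]] = True
            end[loop_sink[side]] = True

    # Helix chains: entered from the source-side loop(s); chained; with an
    # unbounded maximum the last sub-state self-loops.  A chain may start
    # (leading helix) and may end once past the minimum (trailing helix).
    for (src, dst), chain in m_chain.items():
        preds[chain[0]].extend(loop_sources[src])
        start[chain[0]] = True
        for k in range(1, len(chain)):
            preds[chain[k]].append(chain[k - 1])
        if unbounded:
            preds[chain[-1]].append(chain[-1])
        for k in helix_exit_ks:
            end[chain[k - 1]] = True

    # SP chain: only enterable at the very first residue.
    start[s_chain[0]] = True
    for k in range(1, len(s_chain)):
        preds[s_chain[k]].append(s_chain[k - 1])
    for k in sp_exit_ks:
        end[s_chain[k - 1]] = True

    return _Machine(
        labels=tuple(labels),
        preds=tuple(tuple(sorted(pp)) for pp in preds),
        start=tuple(start),
        end=tuple(end),
    )


def decode_consensus(
    profile: TopologyProfile, cfg: Optional[ConsensusConfig] = None
) -> ConsensusResult:
    """Globally optimal grammar-valid topology for a profile.

    Maximizes the mean log smoothed profile value over all label strings
    accepted by the grammar state machine; deterministic (fixed tie-break)
    and exact — the dynamic program searches the full path space.
    """
    cfg = cfg or ConsensusConfig()
    p = profile.fractions
    L = profile.length
    eps = cfg.pseudocount
    with np.errstate(divide="ignore"):
        logp = np.log((p + eps) / (1.0 + 4.0 * eps))  # (L, 4)

    m = _build_machine(cfg.grammar)
    n = len(m.labels)
    lab_idx = np.fromiter((LABEL_TO_COL[l] for l in m.labels), dtype=np.int64, count=n)
    emit = logp[:, lab_idx]  # (L, n)

    max_p = max((len(pp) for pp in m.preds), default=1) or 1
    P = np.full((n, max_p), n, dtype=np.int64)  # n == sentinel (-inf)
    for s, pp in enumerate(m.preds):
        P[s, : len(pp)] = pp

    start_mask = np.array(m.start)
    end_mask = np.array(m.end)
    NEG = -np.inf
    score = np.where(start_mask, emit[0], NEG)
    back = np.empty((L, n), dtype=np.int64)
    rows = np.arange(n)
    for c in range(1, L):
        ext = np.append(score, NEG)
        cand = ext[P]  # (n, max_p)
        j = np.argmax(cand, axis=1)  # first max -> lowest-index predecessor
        back[c] = P[rows, j]
        score = emit[c] + cand[rows, j]

    final = np.where(end_mask, score, NEG)
    best = float(np.max(final))
    if not np.isfinite(best):
        raise ValueError(
            f"no grammar-valid topology of length {L} under this grammar"
        )
    s = int(np.argmax(final))  # first max -> lowest state index
    path = [0] * L
    path[L - 1] = s
    for c in range(L - 1, 0, -1):
        s = int(back[c, s])
        path[c - 1] = s

    labels = "".join(m.labels[k] for k in path)
    topo = TopologyString(profile.protein_id or "consensus", labels)
    assert validate_topology(topo, cfg.grammar).valid
    col = np.fromiter((LABEL_TO_COL[c] for c in labels), dtype=np.int64, count=L)
    agreement = p[np.arange(L), col].copy()
    return ConsensusResult(
        topology=topo,
        log_geometric_mean_score=score_path(profile, topo, eps),
        per_residue_agreement=agreement,
    )


def consensus(
    predictions: Sequence[TopologyString], cfg: Optional[ConsensusConfig] = None
) -> ConsensusResult:
    """Convenience: :func:`build_profile` followed by :func:`decode_consensus`."""
    return decode_consensus(build_profile(predictions), cfg)
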