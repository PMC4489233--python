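"""Seeded synthetic proteins, topologies and noisy per-method predictions.

Every stage of the library is testable without external predictors: this
module draws ground-truth topologies that satisfy the grammar, attaches
amino-acid sequences whose membrane helices are hydrophobic-enriched (so
insertion free-energy tracks dip inside true helices), and derives
per-method predictions by applying the error modes real topology
predictors exhibit — signal peptides swapped with N-terminal helices,
missed or spurious helices, missed or spurious signal peptides, jittered
segment boundaries, and globally inverted orientation.

Each noise operation repairs the topology afterwards (side alternation
restored, grammar length minima respected), so perturbed predictions stay
grammar-valid and length-preserving.  Everything is a pure function of
``(SimConfig, protein index, method index)``.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AMINO_ACIDS,
    DEFAULT_GRAMMAR,
    GrammarConfig,
    ProteinRecord,
    TopologyClass,
    TopologyString,
    segments_from_labels,
    validate_topology,
)
from .evaluation import CLASS_ORDER

# Membrane-helix amino-acid bias: strongly hydrophobic residues dominate,
# charged residues are rare.  Loops and signal peptides with these weights
# vs uniform give clearly separated insertion free-energy distributions.
_HELIX_WEIGHTS = {
    "A": 8.0, "C": 2.0, "D": 0.4, "E": 0.4, "F": 9.0, "G": 5.0, "H": 0.8,
    "I": 12.0, "K": 0.4, "L": 16.0, "M": 3.0, "N": 0.8, "P": 0.8, "Q": 0.8,
    "R": 0.4, "S": 3.0, "T": 4.0, "V": 11.0, "W": 3.0, "Y": 3.0,
}
_AA = np.array(list(AMINO_ACIDS))
_HELIX_P = np.array([_HELIX_WEIGHTS[a] for a in AMINO_ACIDS])
_HELIX_P = _HELIX_P / _HELIX_P.sum()
_LOOP_P = np.full(len(_AA), 1.0 / len(_AA))

Run = List  # [label, length]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic ensemble.

    ``class_mix`` orders fractions as (TM, SP+TM, SP-only, globular); the
    default mirrors a proteome-like composition dominated by globular and
    secreted proteins.  Noise probabilities are per-method, applied
    independently per protein; ``boundary_shift_max`` jitters every segment
    boundary uniformly in ``[-max, +max]``.
    """

    seed: int = 0
    n_proteins: int = 500
    class_mix: Tuple[float, float, float, float] = (0.05, 0.11, 0.32, 0.52)
    helices_range: Tuple[int, int] = (1, 7)
    helix_len_range: Tuple[int, int] = (15, 30)
    loop_len_range: Tuple[int, int] = (5, 60)
    sp_len_range: Tuple[int, int] = (10, 40)
    globular_len_range: Tuple[int, int] = (50, 300)
    secreted_tail_range: Tuple[int, int] = (40, 200)
    boundary_shift_max: int = 3
    helix_drop_prob: float = 0.05
    helix_add_prob: float = 0.02
    sp_tm_swap_prob: float = 0.05
    sp_drop_prob: float = 0.03
    sp_add_prob: float = 0.02
    invert_prob: float = 0.02
    n_methods: int = 5
    grammar: GrammarConfig = DEFAULT_GRAMMAR

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_methods < 1:
            raise ValueError("n_proteins and n_methods must be >= 1")
        if len(self.class_mix) != 4 or any(f < 0 for f in self.class_mix) or not sum(self.class_mix):
            raise ValueError("class_mix must be 4 non-negative fractions, not all zero")
        for name in (
            "helices_range", "helix_len_range", "loop_len_range",
            "sp_len_range", "globular_len_range", "secreted_tail_range",
        ):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"infeasible {name}: ({lo}, {hi})")
        if self.helix_len_range[0] < self.grammar.min_helix_len:
            raise ValueError("helix_len_range below grammar minimum helix length")
        if (self.grammar.max_helix_len is not None
                and self.helix_len_range[1] > self.grammar.max_helix_len):
            raise ValueError("helix_len_range above grammar maximum helix length")
        if not (self.grammar.min_sp_len <= self.sp_len_range[0]
                and self.sp_len_range[1] <= self.grammar.max_sp_len):
            raise ValueError("sp_len_range outside grammar signal-peptide bounds")
        for name in (
            "helix_drop_prob", "helix_add_prob", "sp_tm_swap_prob",
            "sp_drop_prob", "sp_add_prob", "invert_prob",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.boundary_shift_max < 0:
            raise ValueError("boundary_shift_max must be >= 0")


def _randint(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _flip_label(label: str) -> str:
    return {"i": "o", "o": "i"}.get(label, label)


def _flip_io(runs: Sequence[Run]) -> List[Run]:
    return [[_flip_label(l), n] for l, n in runs]


def _normalize(runs: Sequence[Run]) -> List[Run]:
    out: List[Run] = []
    for l, n in runs:
        if n <= 0:
            continue
        if out and out[-1][0] == l:
            out[-1][1] += n
        else:
            out.append([l, n])
    return out


def _runs_to_labels(runs: Sequence[Run]) -> str:
    return "".join(l * n for l, n in runs)


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

def _sample_runs(cls: TopologyClass, cfg: SimConfig, rng: np.random.Generator) -> List[Run]:
    loop = lambda: _randint(rng, *cfg.loop_len_range)
    if cls is TopologyClass.GLOBULAR:
        side = str(rng.choice(["i", "o"]))
        return [[side, _randint(rng, *cfg.globular_len_range)]]
    if cls is TopologyClass.SP_ONLY:
        return [
            ["S", _randint(rng, *cfg.sp_len_range)],
            [cfg.grammar.post_sp_side, _randint(rng, *cfg.secreted_tail_range)],
        ]
    runs: List[Run] = []
    if cls is TopologyClass.SP_TM:
        runs.append(["S", _randint(rng, *cfg.sp_len_range)])
        side = cfg.grammar.post_sp_side
    else:
        side = str(rng.choice(["i", "o"]))
    runs.append([side, loop()])
    for _ in range(_randint(rng, *cfg.helices_range)):
        runs.append(["M", _randint(rng, *cfg.helix_len_range)])
        side = _flip_label(side)
        runs.append([side, loop()])
    return runs


def _sample_sequence(runs: Sequence[Run], rng: np.random.Generator) -> str:
    parts = []
    for l, n in runs:
        p = _HELIX_P if l in ("M", "S") else _LOOP_P
        parts.append("".join(rng.choice(_AA, size=n, p=p)))
    return "".join(parts)


def generate_truth(cfg: SimConfig) -> List[Tuple[ProteinRecord, TopologyString]]:
    """Draw ``n_proteins`` grammar-valid (sequence, topology) pairs."""
    mix = np.asarray(cfg.class_mix, dtype=float)
    mix = mix / mix.sum()
    out: List[Tuple[ProteinRecord, TopologyString]] = []
    for k in range(cfg.n_proteins):
        rng = np.random.default_rng([cfg.seed, 0, k])
        cls = CLASS_ORDER[int(rng.choice(4, p=mix))]
        runs = _sample_runs(cls, cfg, rng)
        pid = f"SYN{k:05d}"
        labels = _runs_to_labels(runs)
        out.append((ProteinRecord(pid, _sample_sequence(runs, rng)),
                    TopologyString(pid, labels)))
    return out


# --------------------------------------------------------------------------
# Per-method noise
# --------------------------------------------------------------------------

def _swap_sp_tm(runs: List[Run], cfg: SimConfig, rng: np.random.Generator) -> List[Run]:
    """Relabel the signal peptide as a leading helix, or the N-terminal
    helix (plus any short loop before it) as a signal peptide."""
    g = cfg.grammar
    labels = [l for l, _ in runs]
    if labels[0] == "S":
        s_len = runs[0][1]
        deficit = max(0, g.min_helix_len - s_len)
        if len(runs) < 2 or runs[1][1] <= deficit:
            return runs  # cannot repair to a legal helix; skip
        return _normalize(
            [["M", s_len + deficit], [runs[1][0], runs[1][1] - deficit]] + runs[2:]
        )
    if labels[0] == "M":
        lead = 1
    elif len(runs) >= 2 and labels[1] == "M":
        lead = 2
    else:
        return runs  # no N-terminal helix to confuse
    combined = sum(n for _, n in runs[:lead])
    s_len = min(max(combined, g.min_sp_len), g.max_sp_len)
    leftover = combined - s_len
    rest = [list(r) for r in runs[lead:]]
    if rest and rest[0][0] != g.post_sp_side:
        rest = _flip_io(rest)
    if rest:
        if leftover:
            rest[0][1] += leftover
    elif leftover:
        rest = [[g.post_sp_side, leftover]]
    return _normalize([["S", s_len]] + rest)


def _drop_sp(runs: List[Run]) -> List[Run]:
    if len(runs) == 1:
        return [["o", runs[0][1]]]
    return _normalize([[runs[1][0], runs[0][1] + runs[1][1]]] + runs[2:])


def _add_sp(runs: List[Run], cfg: SimConfig, rng: np.random.Generator) -> List[Run]:
    g = cfg.grammar
    first = runs[0]
    if first[0] == "M":
        return runs
    want = _randint(rng, *cfg.sp_len_range)
    s_len = min(want, first[1] - 1, g.max_sp_len)
    if s_len < g.min_sp_len:
        return runs
    rest = [[first[0], first[1] - s_len]] + [list(r) for r in runs[1:]]
    if rest[0][0] != g.post_sp_side:
        rest = _flip_io(rest)
    return _normalize([["S", s_len]] + rest)


def _drop_helices(runs: List[Run], cfg: SimConfig, rng: np.random.Generator) -> List[Run]:
    m_idx = [k for k, (l, _) in enumerate(runs) if l == "M"]
    if not m_idx:
        return runs
    drops = rng.random(len(m_idx)) < cfg.helix_drop_prob
    if not drops.any():
        return runs
    runs = [list(r) for r in runs]
    for ordinal in reversed(range(len(m_idx))):
        if not drops[ordinal]:
            continue
        k = m_idx[ordinal]
        if k > 0 and runs[k - 1][0] in "io":
            runs[k][0] = runs[k - 1][0]
            runs[k + 1:] = _flip_io(runs[k + 1:])
        elif k + 1 < len(runs):
            runs[k][0] = runs[k + 1][0]
        else:
            runs[k][0] = "o"
    return _normalize(runs)


def _add_helices(runs: List[Run], cfg: SimConfig, rng: np.random.Generator) -> List[Run]:
    g = cfg.grammar
    out: List[Run] = []
    flip = False
    for l, n in runs:
        lab = _flip_label(l) if flip else l
        if lab in "io" and n >= g.min_helix_len + 2 and rng.random() < cfg.helix_add_prob:
            h = min(_randint(rng, *cfg.helix_len_range), n - 2)
            left = _randint(rng, 1, n - h - 1)
            out += [[lab, left], ["M", h], [_flip_label(lab), n - h - left]]
            flip = not flip
        else:
            out.append([lab, n])
    return _normalize(out)


def _shift_boundaries(runs: List[Run], cfg: SimConfig, rng: np.random.Generator) -> List[Run]:
    m = cfg.boundary_shift_max
    if m <= 0 or len(runs) < 2:
        return runs
    g = cfg.grammar
    labels = [l for l, _ in runs]
    lengths = [n for _, n in runs]
    L = sum(lengths)
    bounds = np.cumsum(lengths)[:-1] + rng.integers(-m, m + 1, size=len(runs) - 1)

    def minlen(label: str) -> int:
        if label == "S":
            return g.min_sp_len
        if label == "M":
            return g.min_helix_len
        return 1

    prev = 0
    for j in range(len(bounds)):
        lo = prev + minlen(labels[j])
        if bounds[j] < lo:
            bounds[j] = lo
        prev = bounds[j]
    nxt = L
    for j in reversed(range(len(bounds))):
        hi = nxt - minlen(labels[j + 1])
        if bounds[j] > hi:
            bounds[j] = hi
        nxt = bounds[j]

    new_lengths = np.diff(np.concatenate(([0], bounds, [L])))
    ok = all(
        n >= minlen(l)
        and not (l == "S" and n > g.max_sp_len)
        and not (l == "M" and g.max_helix_len is not None and n > g.max_helix_len)
        for l, n in zip(labels, new_lengths)
    )
    if not ok:
        return runs  # jitter would break the grammar; keep original boundaries
    return [[l, int(n)] for l, n in zip(labels, new_lengths)]


def perturb(
    truth: TopologyString,
    cfg: SimConfig,
    method_index: int,
    rng: Optional[np.random.Generator] = None,
) -> TopologyString:
    """One method's noisy view of a grammar-valid truth topology.

    Operations in fixed order: SP <-> N-terminal-helix swap, SP drop/add,
    helix drops, helix additions, boundary jitter, global i/o inversion
    (inversion is skipped for SP-bearing topologies, whose post-SP side is
    pinned by the grammar).  Length-preserving, and the output is again
    grammar-valid.
    """
    if rng is None:
        pid_hash = zlib.crc32(truth.protein_id.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([cfg.seed, 1 + method_index, pid_hash])
    runs: List[Run] = [[s.label, len(s)] for s in segments_from_labels(truth)]
    if rng.random() < cfg.sp_tm_swap_prob:
        runs = _swap_sp_tm(runs, cfg, rng)
    if runs[0][0] == "S":
        if rng.random() < cfg.sp_drop_prob:
            runs = _drop_sp(runs)
    elif rng.random() < cfg.sp_add_prob:
        runs = _add_sp(runs, cfg, rng)
    runs = _drop_helices(runs, cfg, rng)
    runs = _add_helices(runs, cfg, rng)
    runs = _shift_boundaries(runs, cfg, rng)
    if runs[0][0] != "S" and rng.random() < cfg.invert_prob:
        runs = _flip_io(runs)
    out = TopologyString(truth.protein_id, _runs_to_labels(runs))
    assert len(out) == len(truth)
    return out


# --------------------------------------------------------------------------
# Whole ensembles
# --------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class SimulatedDataset:
    proteins: Tuple[ProteinRecord, ...]
    truths: Dict[str, TopologyString]
    predictions: Dict[str, List[TopologyString]]  # pid -> one per method

    @property
    def method_names(self) -> List[str]:
        n = len(next(iter(self.predictions.values())))
        return [f"method_{k + 1}" for k in range(n)]


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Truth ensemble plus ``n_methods`` perturbed predictions per protein."""
    pairs = generate_truth(cfg)
    truths = {rec.id: topo for rec, topo in pairs}
    predictions = {
        rec.id: [perturb(topo, cfg, m) for m in range(cfg.n_methods)]
        for rec, topo in pairs
    }
    return SimulatedDataset(
        proteins=tuple(rec for rec, _ in pairs),
        truths=truths,
        predictions=predictions,
    )
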