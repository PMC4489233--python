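"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they verify: the decoder oracle
enumerates every label string and keeps the grammar-valid ones; scores are
direct per-column sums; the window-sum oracle is a double loop.
"""
from functools import lru_cache
from itertools import product

import numpy as np

from topoconsensus.core import GrammarConfig, validate_topology

_COL = {"S": 0, "M": 1, "i": 2, "o": 3}


@lru_cache(maxsize=None)
def valid_strings(length: int, grammar: GrammarConfig):
    """All grammar-valid label strings of a given length (exhaustive)."""
    out = []
    for chars in product("SMio", repeat=length):
        s = "".join(chars)
        if validate_topology(s, grammar).valid:
            out.append(s)
    return tuple(out)


def direct_score(fractions: np.ndarray, labels: str, eps: float) -> float:
    """Mean log smoothed fraction along a path, summed column by column."""
    total = 0.0
    for c, ch in enumerate(labels):
        total += np.log((fractions[c, _COL[ch]] + eps) / (1.0 + 4.0 * eps))
    return total / len(labels)


def brute_force_best(fractions: np.ndarray, grammar: GrammarConfig, eps: float):
    """Best (score, string) over every grammar-valid string of this length."""
    best_score, best_string = -np.inf, None
    for s in valid_strings(fractions.shape[0], grammar):
        sc = direct_score(fractions, s, eps)
        if sc > best_score:
            best_score, best_string = sc, s
    return best_score, best_string


def brute_force_dg(sequence: str, per_residue: dict, window: int, weights=None):
    """Windowed sums by explicit double loop."""
    if weights is None:
        weights = [1.0] * window
    vals = []
    for c in range(window // 2, len(sequence) - window // 2):
        total = 0.0
        for j in range(window):
            total += weights[j] * per_residue[sequence[c - window // 2 + j]]
        vals.append(total)
    return vals
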