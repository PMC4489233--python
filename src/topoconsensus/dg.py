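"""Free energy of membrane insertion along a sequence.

A sliding window (21 residues by default, matching the length of a typical
membrane-spanning helix) is centered on each position and the per-residue
contributions of a hydrophobicity scale are summed, optionally with
positional weights.  Low (negative) values mark stretches that partition
favourably into the membrane; the track dips inside true TM helices.

The packaged scale (:func:`biological_scale`) carries the
position-independent contributions of the biological, translocon-derived
hydrophobicity scale in kcal/mol; any user scale in the same simple
``LETTER<TAB>value`` format can be substituted.  Windows extending past
either terminus are not computed, so a sequence shorter than the window
yields an empty track.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class DgScale:
    """Per-residue insertion free-energy contributions plus window geometry.

    ``unknown_policy`` controls letters outside the 20 standard codes
    (X/B/Z): ``"mean"`` substitutes the mean of the 20 standard values with
    a logged warning, ``"error"`` raises.
    """

    name: str
    per_residue: Dict[str, float]
    window: int = 21
    positional_weights: Optional[Tuple[float, ...]] = None
    unknown_policy: str = "mean"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and positive, got {self.window}")
        missing = sorted(set(AMINO_ACIDS) - set(self.per_residue))
        if missing:
            raise ValueError(f"scale missing residue {', '.join(missing)}")
        if self.positional_weights is not None:
            w = tuple(float(x) for x in self.positional_weights)
            if len(w) != self.window:
                raise ValueError(
                    f"positional_weights length {len(w)} != window {self.window}"
                )
            object.__setattr__(self, "positional_weights", w)
        if self.unknown_policy not in ("mean", "error"):
            raise ValueError("unknown_policy must be 'mean' or 'error'")

    @property
    def mean_value(self) -> float:
        return float(np.mean([self.per_residue[a] for a in AMINO_ACIDS]))

    def value(self, letter: str) -> float:
        """Contribution of one residue, applying the unknown-letter policy."""
        try:
            return self.per_residue[letter]
        except KeyError:
            if self.unknown_policy == "error":
                raise ValueError(
                    f"scale {self.name!r} has no value for residue {letter!r}"
                ) from None
            logger.warning(
                "scale %r: residue %r gets the mean contribution %.3f",
                self.name, letter, self.mean_value,
            )
            return self.mean_value


@dataclass(frozen=True, eq=False)
class DgTrack:
    """Windowed insertion free energies for one protein.

    ``values[k]`` belongs to 0-based center ``offset + k`` where
    ``offset = window // 2``; there are ``max(0, L - window + 1)`` centers.
    """

    protein_id: str
    values: np.ndarray
    window: int

    @property
    def offset(self) -> int:
        return self.window // 2

    @property
    def centers(self) -> np.ndarray:
        """0-based window-center positions."""
        return np.arange(len(self.values)) + self.offset

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[Tuple[int, float]]:
        return iter(zip(self.centers.tolist(), self.values.tolist()))


def load_scale(
    path: Union[str, Path],
    window: int = 21,
    name: Optional[str] = None,
    positional_weights: Optional[Sequence[float]] = None,
    unknown_policy: str = "mean",
) -> DgScale:
    """Read a ``LETTER<TAB>value`` scale file ('#' starts a comment).

    All 20 standard residues must be present; duplicates, non-numeric
    values and malformed lines are reported with their line number.
    """
    path = Path(path)
    per_residue: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'LETTER<TAB>value', got {raw.rstrip()!r}"
                )
            letter, value = parts
            if len(letter) != 1:
                raise ValueError(f"{path}:{lineno}: residue code {letter!r} not a single letter")
            if letter in per_residue:
                raise ValueError(f"{path}:{lineno}: duplicate residue {letter!r}")
            try:
                per_residue[letter] = float(value)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {value!r} for residue {letter!r}"
                ) from None
    return DgScale(
        name=name or path.stem,
        per_residue=per_residue,
        window=window,
        positional_weights=tuple(positional_weights) if positional_weights else None,
        unknown_policy=unknown_policy,
    )


def biological_scale(window: int = 21) -> DgScale:
    """The packaged biological (translocon) hydrophobicity scale."""
    ref = resources.files("topoconsensus") / "data" / "biological_hydrophobicity.tsv"
    with resources.as_file(ref) as path:
        return load_scale(path, window=window, name="biological_hydrophobicity")


def dg_track(protein: ProteinRecord, scale: DgScale) -> DgTrack:
    """Sliding-window insertion free energy for every full-window center.

    ``dG(c) = sum_j w[j] * g(seq[c - window//2 + j])`` for centers
    ``window//2 .. L - window//2 - 1``; empty when ``L < window``.
    """
    W = scale.window
    seq = protein.sequence
    if len(seq) < W:
        return DgTrack(protein.id, np.empty(0, dtype=float), W)
    g = np.fromiter((scale.value(c) for c in seq), dtype=float, count=len(seq))
    if scale.positional_weights is None:
        w = np.ones(W, dtype=float)
    else:
        w = np.asarray(scale.positional_weights, dtype=float)
    # sliding dot product == correlation == convolution with reversed weights
    vals = np.convolve(g, w[::-1], mode="valid")
    return DgTrack(protein.id, vals, W)


def write_dg_tsv(tracks: Sequence[DgTrack], path: Union[str, Path]) -> None:
    """Write tracks as ``protein_id<TAB>position(1-based)<TAB>dG`` rows."""
    with open(path, "w") as fh:
        fh.write("#protein_id\tposition\tdG\n")
        for track in tracks:
            for center, val in track:
                fh.write(f"{track.protein_id}\t{center + 1}\t{val:.4f}\n")
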