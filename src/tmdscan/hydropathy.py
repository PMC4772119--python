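"""Hydropathy scales and windowed hydropathy profiles.

Two scales are bundled as plain-text data files: the GES
(Goldman-Engelman-Steitz) water-to-bilayer transfer free-energy scale
(kcal/mol) and the Kyte-Doolittle hydropathy index. Both are oriented so
hydrophobic residues score positive; a residue is classified hydrophobic
when its score exceeds the scale's threshold (0 by default), so profiles
cross 0 at the water/membrane boundary.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import ALPHABET

_SCALE_FILES = {"GES": "ges.tsv", "KD": "kd.tsv"}
_SCALE_UNITS = {"GES": "kcal/mol", "KD": "index"}


@dataclasses.dataclass(frozen=True)
class HydropathyScale:
    """A residue -> hydrophobicity score map with a classification threshold."""

    name: str
    values: dict[str, float]
    units: str
    hydrophobic_threshold: float = 0.0

    def __post_init__(self) -> None:
        missing = ALPHABET - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name}: missing residues {sorted(missing)}")
        extra = set(self.values) - ALPHABET
        if extra:
            raise ValueError(f"scale {self.name}: unknown residues {sorted(extra)}")

    def score(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"residue {residue!r} not in the amino-acid alphabet"
            ) from None

    def is_hydrophobic(self, residue: str) -> bool:
        """True iff the residue scores strictly above the threshold."""
        return self.score(residue) > self.hydrophobic_threshold

    def scores(self, sequence: str) -> np.ndarray:
        return np.array([self.score(c) for c in sequence], dtype=float)


@dataclasses.dataclass(frozen=True)
class HydropathyProfile:
    """Windowed mean hydropathy along a sequence; positions are 1-based."""

    positions: np.ndarray
    scores: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.scores)


def load_scale_file(path: str | Path, name: str, units: str = "", threshold: float = 0.0) -> HydropathyScale:
    """Load a residue<TAB>score scale table (``#`` comments allowed)."""
    values: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        residue, score = line.split("\t")
        values[residue.strip()] = float(score)
    return HydropathyScale(name, values, units, threshold)


def get_scale(name: str, hydrophobic_threshold: float = 0.0) -> HydropathyScale:
    """Return a bundled scale by name ("GES" or "KD")."""
    key = name.upper()
    if key not in _SCALE_FILES:
        raise ValueError(
            f"unknown hydropathy scale {name!r}; supported: {', '.join(sorted(_SCALE_FILES))}"
        )
    ref = resources.files("tmdscan.data") / _SCALE_FILES[key]
    with resources.as_file(ref) as path:
        return load_scale_file(path, key, _SCALE_UNITS[key], hydrophobic_threshold)


def is_hydrophobic(scale: HydropathyScale, residue: str) -> bool:
    return scale.is_hydrophobic(residue)


def windowed_profile(
    sequence: str, scale: HydropathyScale, window: int = 18
) -> HydropathyProfile:
    """Sliding-window mean hydropathy.

    The score at 1-based position ``i`` is the arithmetic mean of the scale
    values of residues ``i .. i+window-1``; the profile has
    ``len(sequence) - window + 1`` positions.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(sequence) < window:
        raise ValueError(
            f"sequence length {len(sequence)} is shorter than window {window}"
        )
    scores = scale.scores(sequence)
    means = np.lib.stride_tricks.sliding_window_view(scores, window).mean(axis=1)
    positions = np.arange(1, len(means) + 1)
    return HydropathyProfile(positions=positions, scores=means, window=window)
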