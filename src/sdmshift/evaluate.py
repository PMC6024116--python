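"""Model evaluation and map binarization.

AUC here is the presence-versus-background discrimination probability
(Mann-Whitney formulation, ties counted one half): the chance that a
random presence cell receives a higher suitability score than a random
background cell.  Raw probability maps are turned into binary
suitable/nonsuitable maps at the MaxSSS threshold — the observed score
that maximizes sensitivity + specificity, the recommended binarization
rule for presence-only models — and suitable area is the count of
suitable cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grid import Grid

__all__ = ["SuitabilityMap", "BinaryMap", "auc", "maxsss_threshold",
           "binarize", "suitable_area"]


@dataclass
class SuitabilityMap:
    """Per-cell presence probability on a grid; NaN outside the mask."""

    grid: Grid
    values: np.ndarray   # float array, NaN on masked cells
    mask: np.ndarray     # True = excluded from the modeling extent
    period: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        inside = self.values[~self.mask]
        if inside.size and (np.nanmin(inside) < -1e-12 or np.nanmax(inside) > 1 + 1e-12):
            raise ValueError("suitability values must lie in [0, 1]")

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def at_cells(self, flat_cells: np.ndarray) -> np.ndarray:
        return self.values.ravel()[np.asarray(flat_cells, dtype=int)]


@dataclass
class BinaryMap:
    """Suitable / nonsuitable / masked partition of a grid."""

    grid: Grid
    suitable: np.ndarray  # bool; False on masked cells too
    mask: np.ndarray
    threshold: float
    period: str = ""

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.suitable & self.mask):
            raise ValueError("masked cells cannot be suitable")


def auc(pos_scores: np.ndarray, bg_scores: np.ndarray) -> float:
    """Probability a random presence outscores a random background (ties ½).

    Computed from midranks: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_bg),
    the Mann-Whitney U statistic normalized to [0, 1].
    """
    pos = np.asarray(pos_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if pos.size == 0 or bg.size == 0:
        raise ValueError("both score groups must be nonempty")
    ranks = rankdata(np.concatenate([pos, bg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * bg.size))


def maxsss_threshold(pos_scores: np.ndarray, bg_scores: np.ndarray) -> float:
    """Observed score maximizing sensitivity(t) + specificity(t).

    sensitivity(t) = fraction of presences with score >= t;
    specificity(t) = fraction of backgrounds with score < t.  Candidates
    are the observed scores of both groups; ties take the smallest
    maximizing threshold.
    """
    pos = np.sort(np.asarray(pos_scores, dtype=float))
    bg = np.sort(np.asarray(bg_scores, dtype=float))
    if pos.size == 0 or bg.size == 0:
        raise ValueError("both score groups must be nonempty")
    candidates = np.unique(np.concatenate([pos, bg]))
    # integer counts of pos >= t and bg < t via binary search; comparing
    # n_pos_ge * n_bg + n_bg_lt * n_pos keeps ties exact (no float division)
    n_pos_ge = pos.size - np.searchsorted(pos, candidates, side="left")
    n_bg_lt = np.searchsorted(bg, candidates, side="left")
    total = n_pos_ge * bg.size + n_bg_lt * pos.size
    best = int(np.argmax(total))  # first (smallest) maximizer
    return float(candidates[best])


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Suitable wherever p >= threshold; the mask is preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        suitable = (smap.values >= threshold) & ~smap.mask
    return BinaryMap(grid=smap.grid, suitable=suitable, mask=smap.mask.copy(),
                     threshold=float(threshold), period=smap.period)


def suitable_area(binary: BinaryMap) -> int:
    """Number of suitable cells (pixel count, the Table-2-style area unit)."""
    return int(binary.suitable.sum())
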