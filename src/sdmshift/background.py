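"""Target-group background sampling with survey-effort correction.

Presence-only models need background points describing the available
environment.  Drawing them uniformly would contrast a spatially biased
presence sample against an unbiased background and absorb the survey bias
into the model.  Instead, a Gaussian kernel density estimate over all
*visited* cells (cells holding at least one record of any species in the
occurrence database) serves as a survey-effort proxy, and background cells
are drawn with probability proportional to that effort, so presences and
backgrounds share the same sampling bias.

Background count equals presence count and the draw is replicated
(default 100-fold) with derived seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import EnvStack, Grid, OccurrenceSet

__all__ = ["EffortSurface", "ReplicateSet", "effort_kde", "scott_bandwidth",
           "sample_background", "make_replicates"]


@dataclass
class EffortSurface:
    """Per-cell sampling-effort weights; nonnegative, summing to 1 over
    unmasked cells and exactly 0 on masked cells."""

    grid: Grid
    weights: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.grid.shape:
            raise ValueError("effort surface shape does not match grid")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("effort weights must sum to 1")


@dataclass
class ReplicateSet:
    """Fixed presence cells plus one background cell set per replicate."""

    presence_cells: np.ndarray          # flat cell indices
    background_sets: list[np.ndarray]   # each of size == len(presence_cells)
    seeds: list[int] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.background_sets)


def scott_bandwidth(rows: np.ndarray, cols: np.ndarray) -> float:
    """Scott's rule bandwidth (cell units) for 2-D visited-cell coordinates:
    n^(-1/6) times the pooled per-axis standard deviation."""
    n = len(rows)
    if n < 2:
        return 1.0
    sd = np.sqrt((np.var(rows, ddof=1) + np.var(cols, ddof=1)) / 2.0)
    if sd == 0:
        return 1.0
    return float(sd * n ** (-1.0 / 6.0))


def effort_kde(visited: OccurrenceSet | tuple[np.ndarray, np.ndarray], grid: Grid,
               bandwidth: float | None = None,
               valid_mask: np.ndarray | None = None) -> EffortSurface:
    """Gaussian KDE of visited cells, evaluated at unmasked cell centers.

    ``visited`` is either an OccurrenceSet (of the whole target group, not
    only the focal species) or a (rows, cols) pair.  Bandwidth is in cell
    units; None selects Scott's rule.  The surface is normalized to sum 1
    over unmasked cells.
    """
    if isinstance(visited, OccurrenceSet):
        vr, vc = visited.rows, visited.cols
    else:
        vr, vc = (np.asarray(v, dtype=float) for v in visited)
    if len(vr) < 1:
        raise ValueError("need at least one visited cell")
    if bandwidth is None:
        bandwidth = scott_bandwidth(vr, vc)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    seeds = np.column_stack([vr, vc]).astype(float)
    # kernel sum in chunks to bound memory on large grids
    dens = np.zeros(len(pts))
    inv = -0.5 / bandwidth**2
    for start in range(0, len(seeds), 512):
        block = seeds[start:start + 512]
        d2 = ((pts[:, None, :] - block[None, :, :]) ** 2).sum(axis=2)
        dens += np.exp(inv * d2).sum(axis=1)
    dens = dens.reshape(grid.shape)
    if valid_mask is not None:
        dens = np.where(valid_mask, dens, 0.0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("effort density vanished on all unmasked cells")
    return EffortSurface(grid=grid, weights=dens / total, bandwidth=float(bandwidth))


def sample_background(effort: EffortSurface, n: int, seed: int,
                      exclude_cells: np.ndarray | None = None) -> np.ndarray:
    """Draw n distinct background cells with probability ∝ effort weight.

    ``exclude_cells`` (flat indices — typically the focal species' presence
    cells) are zeroed before the draw.  Returns sorted flat cell indices.
    """
    w = effort.weights.ravel().copy()
    if exclude_cells is not None:
        w[np.asarray(exclude_cells, dtype=int)] = 0.0
    eligible = np.flatnonzero(w > 0)
    if n > eligible.size:
        raise ValueError(f"requested {n} background cells but only {eligible.size} eligible")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=False, p=w[eligible] / w[eligible].sum())
    return np.sort(chosen)


def make_replicates(occ: OccurrenceSet, effort: EffortSurface, n_rep: int = 100,
                    base_seed: int = 0, exclude_presences: bool = True) -> ReplicateSet:
    """Replicate the background draw n_rep times with seeds base_seed + i.

    The presence set is identical across replicates and each background set
    has exactly as many cells as there are presences.
    """
    presence_cells = np.sort(occ.flat_cells)
    exclude = presence_cells if exclude_presences else None
    sets, seeds = [], []
    for i in range(n_rep):
        seed = int(base_seed) + i
        sets.append(sample_background(effort, len(presence_cells), seed, exclude))
        seeds.append(seed)
    return ReplicateSet(presence_cells=presence_cells, background_sets=sets, seeds=seeds)
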