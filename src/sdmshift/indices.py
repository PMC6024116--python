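"""Distribution-change indices and the paired environmental-shift test.

Three indices compare suitability maps p and q between time periods on a
common extent (cells valid in both periods):

* ``E_occupied(p)   = sum_i p_i`` — the probabilistic extent of the
  distribution;
* ``E_instability(q, p) = sum_i |q_i - p_i| / E_occupied(ref)`` — overall
  change in the distribution of presence probabilities;
* ``E_overlap(q, p)     = sum_i p_i q_i   / E_occupied(ref)`` — how much
  the two maps concentrate probability on the same cells.

The reference map for scaling is the present-day ([2005-2012]-style)
period, so instability and overlap are comparable across species.  The
magnitude of between-period environmental change is assessed cellwise by
a Wilcoxon signed-rank paired test on layer values (note: grid cells are
spatially autocorrelated, so the test's independence assumption is
violated; p-values are descriptive, and reports carry that caveat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import SuitabilityMap

__all__ = ["ChangeReport", "e_occupied", "e_instability", "e_overlap",
           "replicate_summary", "wilcoxon_paired", "common_extent_values"]

logger = logging.getLogger(__name__)


def common_extent_values(p: SuitabilityMap, q: SuitabilityMap) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise values of two maps on the intersection of their masks."""
    if p.grid.shape != q.grid.shape:
        raise ValueError("maps are on different grids")
    ok = ~p.mask & ~q.mask
    if not np.any(ok):
        raise ValueError("maps share no unmasked cells")
    return p.values[ok], q.values[ok]


def _values(m) -> np.ndarray:
    if isinstance(m, SuitabilityMap):
        v = m.unmasked_values()
    else:
        v = np.asarray(m, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty extent")
    return v


def e_occupied(p) -> float:
    """Sum of presence probabilities over the (unmasked) extent."""
    return float(np.nansum(_values(p)))


def e_instability(q, p, ref) -> float:
    """Scaled total absolute difference between two suitability maps."""
    qv, pv = _values(q), _values(p)
    if qv.shape != pv.shape:
        raise ValueError("maps must cover identical extents")
    denom = e_occupied(ref)
    if denom <= 0:
        raise ValueError("reference map has zero occupancy; cannot scale")
    return float(np.abs(qv - pv).sum() / denom)


def e_overlap(q, p, ref) -> float:
    """Scaled cellwise-product overlap between two suitability maps."""
    qv, pv = _values(q), _values(p)
    if qv.shape != pv.shape:
        raise ValueError("maps must cover identical extents")
    denom = e_occupied(ref)
    if denom <= 0:
        raise ValueError("reference map has zero occupancy; cannot scale")
    return float((qv * pv).sum() / denom)


def replicate_summary(values) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) over model replicates."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    if v.size < 2:
        logger.warning("single replicate: standard deviation undefined, reported as 0")
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Two-sided exact p over the 2^n equiprobable sign assignments.

    Computed by dynamic programming over the distribution of the
    positive-rank sum; ranks may be midranks (half-integers), so they are
    doubled to integers first.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # dist[s] = number of sign patterns with doubled positive-rank sum s
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2 * w))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(a, b, exact_limit: int = 25) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples; returns (W, p).

    W is the sum of ranks of positive differences b - a after dropping
    zero differences (midranks for tied magnitudes).  The two-sided p is
    exact — full enumeration of the 2^n sign patterns — for up to
    ``exact_limit`` nonzero pairs, and a normal approximation with
    continuity and tie corrections above that.
    """
    from scipy.stats import norm, rankdata

    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return w, _exact_signed_rank_p(ranks, w)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w, 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return w, float(min(1.0, p))


# ---------------------------------------------------------------------------
# Table-2-style report


@dataclass
class ChangeReport:
    """Replicate-aggregated suitable areas and change indices per period.

    ``per_period[period]`` holds {"suitable_area": (mean, sd),
    "e_occupied": (mean, sd)}; ``comparisons[period]`` holds the indices
    of reference-vs-period: {"e_instability": (mean, sd),
    "e_overlap": (mean, sd)}.
    """

    reference: str
    per_period: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    comparisons: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "per_period": {k: {m: list(v) for m, v in d.items()}
                           for k, d in self.per_period.items()},
            "comparisons": {k: {m: list(v) for m, v in d.items()}
                            for k, d in self.comparisons.items()},
        }

    def render(self) -> str:
        """Plain-text matrix in the layout of the replicate-summary table."""
        lines = [f"reference period: {self.reference}", ""]
        header = f"{'period':>12} | {'suitable area':>18} | {'E_occupied':>18}"
        lines += [header, "-" * len(header)]
        for period, d in self.per_period.items():
            sa, eo = d["suitable_area"], d["e_occupied"]
            lines.append(f"{period:>12} | {sa[0]:>10.1f} ± {sa[1]:<6.1f}"
                         f" | {eo[0]:>10.1f} ± {eo[1]:<6.1f}")
        lines.append("")
        header = f"{'comparison':>28} | {'E_instability':>16} | {'E_overlap':>16}"
        lines += [header, "-" * len(header)]
        for period, d in self.comparisons.items():
            ei, ov = d["e_instability"], d["e_overlap"]
            lines.append(f"{self.reference + ' vs ' + period:>28}"
                         f" | {ei[0]:>8.3f} ± {ei[1]:<5.3f}"
                         f" | {ov[0]:>8.3f} ± {ov[1]:<5.3f}")
        return "\n".join(lines) + "\n"
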