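"""Occupied environmental-space analysis.

The realized niche of a modeled species is delineated in a 2-D
environmental subspace (typically the two predictors with the highest
relative influence): every cell classified suitable within a focal
geographic box contributes its predictor-value pair, and the occupied
subspace is the convex hull of that point cloud.  Hull area, area
centroid and their displacement between time periods quantify how the
occupied niche moves under environmental change.  Per-predictor 1-D
density profiles (scaled to maximum 1) describe the occupied value
distribution along each axis.

Axes keep their native units; hull areas are therefore comparable only
within the same predictor pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .evaluate import BinaryMap
from .grid import EnvStack

__all__ = ["NicheHull", "DensityProfile", "occupied_env_points",
           "convex_hull_2d", "compare_hulls", "density_profile",
           "KERGUELEN_BOX"]

#: Default focal box (lat_min, lat_max, lon_min, lon_max): a Kerguelen
#: Plateau-like window.
KERGUELEN_BOX = (-56.0, -46.0, 63.0, 81.0)


@dataclass
class NicheHull:
    """Convex hull of occupied environmental points for one period."""

    predictors: tuple[str, str]
    vertices: np.ndarray      # (k, 2), counterclockwise
    area: float
    centroid: tuple[float, float]
    period: str = ""
    degenerate: bool = False  # fewer than 3 non-collinear points

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class DensityProfile:
    predictor: str
    grid_points: np.ndarray
    density: np.ndarray  # scaled so max == 1

    def peak(self) -> float:
        return float(self.grid_points[int(np.argmax(self.density))])


def occupied_env_points(binary: BinaryMap, stack: EnvStack, predictors: list[str],
                        focal_box: tuple[float, float, float, float] = KERGUELEN_BOX
                        ) -> np.ndarray:
    """Predictor-value tuples of suitable cells inside a geographic box.

    Returns an (n_points, len(predictors)) array; empty (0, p) when no
    suitable cell falls in the box.
    """
    for name in predictors:
        if name not in stack:
            raise ValueError(f"predictor {name!r} not in stack")
    lat_min, lat_max, lon_min, lon_max = focal_box
    lon, lat = stack.grid.cell_centers()
    sel = (binary.suitable & (lat >= lat_min) & (lat <= lat_max)
           & (lon >= lon_min) & (lon <= lon_max) & stack.valid_mask())
    return np.column_stack([stack[name].values[sel] for name in predictors])


def _monotone_chain(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone-chain convex hull; counterclockwise vertices."""
    pts = np.unique(points, axis=0)  # sorts lexicographically
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.array(lower[:-1] + upper[:-1])


def convex_hull_2d(points: np.ndarray, predictors: tuple[str, str] = ("x", "y"),
                   period: str = "") -> NicheHull:
    """Convex hull with shoelace area and polygon area centroid.

    Degenerate inputs (one point, collinear points) are flagged; their
    area is 0 and the centroid falls back to the point mean.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    verts = _monotone_chain(pts)
    if len(verts) < 3:
        return NicheHull(predictors=predictors, vertices=verts, area=0.0,
                         centroid=tuple(pts.mean(axis=0)), period=period,
                         degenerate=True)
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()  # positive for counterclockwise vertices
    if abs(area) < 1e-300:
        return NicheHull(predictors=predictors, vertices=verts, area=0.0,
                         centroid=tuple(pts.mean(axis=0)), period=period,
                         degenerate=True)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return NicheHull(predictors=predictors, vertices=verts, area=float(abs(area)),
                     centroid=(float(cx), float(cy)), period=period)


def compare_hulls(hulls: dict[str, NicheHull]) -> dict[str, dict]:
    """Pairwise hull comparison across periods.

    For every ordered pair (earlier key, later key) of the input dict:
    centroid displacement vector and magnitude, area ratio (second /
    first; inf for a degenerate first hull) and intersection area by
    polygon clipping.
    """
    from shapely.geometry import Polygon

    keys = list(hulls)
    if len(keys) < 2:
        raise ValueError("need hulls for at least two periods")
    pred = hulls[keys[0]].predictors
    for h in hulls.values():
        if h.predictors != pred:
            raise ValueError("hulls must share the predictor pair")

    def poly(h: NicheHull):
        if h.degenerate or len(h.vertices) < 3:
            return None
        return Polygon(h.vertices)

    out: dict[str, dict] = {}
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            ha, hb = hulls[ka], hulls[kb]
            dx = hb.centroid[0] - ha.centroid[0]
            dy = hb.centroid[1] - ha.centroid[1]
            pa, pb = poly(ha), poly(hb)
            inter = float(pa.intersection(pb).area) if pa is not None and pb is not None else 0.0
            ratio = hb.area / ha.area if ha.area > 0 else float("inf")
            out[f"{ka} vs {kb}"] = {
                "displacement": (float(dx), float(dy)),
                "displacement_magnitude": float(np.hypot(dx, dy)),
                "area_ratio": float(ratio),
                "intersection_area": inter,
            }
    return out


def density_profile(values: np.ndarray, grid_points: np.ndarray | None = None,
                    bandwidth: float | None = None, predictor: str = "") -> DensityProfile:
    """1-D Gaussian KDE of occupied values, scaled to maximum 1.

    ``bandwidth`` is the kernel standard deviation in predictor units;
    None uses Scott's rule.  A constant sample gets a unit spike at its
    value on a small symmetric window.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("need at least one value")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    spread = v.std()
    if spread == 0 and bandwidth is None:
        bandwidth = 1.0
    if grid_points is None:
        half_width = 3.0 * (bandwidth if bandwidth is not None else max(spread, 1e-6))
        # odd point count so a symmetric window hits its center exactly
        grid_points = np.linspace(v.min() - half_width, v.max() + half_width, 513)
    grid_points = np.asarray(grid_points, dtype=float)
    if v.size == 1 or spread == 0:
        dens = np.exp(-0.5 * ((grid_points - v[0]) / (bandwidth or 1.0)) ** 2)
    else:
        bw_method = (bandwidth / spread) if bandwidth is not None else "scott"
        kde = gaussian_kde(v, bw_method=bw_method)
        dens = kde(grid_points)
    m = dens.max()
    if m <= 0:
        raise ValueError("density vanished on the evaluation grid")
    return DensityProfile(predictor=predictor, grid_points=grid_points, density=dens / m)
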