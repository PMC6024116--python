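"""Ground-truth recovery experiments on the virtual-species world.

Two seeded, self-contained experiments quantify whether the modelling
chain recovers what was planted in the synthetic data:

* :func:`niche_recovery_trial` — a narrow Gaussian niche on two
  informative descriptors among three spatially correlated noise
  descriptors, sampled with northeast-biased survey effort; measures
  held-out AUC and the relative-influence share of the informative pair.

* :func:`shift_recovery_trial` — a temperature-limited species in a
  present/future stack pair differing by a uniform warming; measures the
  sign of the projected latitudinal range shift, the temperature-axis
  displacement of the occupied-niche hull for a non-dispersing
  population (which must equal the imposed warming), and whether
  between-period instability exceeds between-replicate noise.

Both return plain dicts of scalars so they can be aggregated over seeds.
"""

from __future__ import annotations

import numpy as np

from . import simulate as sim
from .background import effort_kde, sample_background
from .brt import BRTConfig, fit_brt, predict_map, relative_influence
from .evaluate import auc, binarize, maxsss_threshold, suitable_area
from .grid import Grid
from .indices import e_instability
from .niche import convex_hull_2d, occupied_env_points

__all__ = ["niche_recovery_trial", "shift_recovery_trial"]

#: Niche widths used by the recovery experiments.  Held-out AUC is bounded
#: by how much of the domain the species occupies (AUC <= 1 - alpha/2), so
#: the recovery species is narrow: ~0.4 degC / 0.1 PSU tolerances on an
#: 8 degC x 0.5 PSU domain.
_RECOVERY_TOL = {"temperature": 0.4, "salinity": 0.1}


def _survey(stack, grid: Grid, suitability: np.ndarray, n_presences: int,
            n_visits: int, effort_bias: float, seed: int):
    """Biased visits -> effort KDE -> presences and one background set."""
    ok = stack.valid_mask()
    lon, lat = grid.cell_centers()
    bias = np.exp(effort_bias * ((lat - lat.min()) + (lon - lon.min())))
    bias = np.where(ok, bias, 0.0)
    rng = np.random.default_rng(seed)
    visits = rng.choice(grid.n_rows * grid.n_cols, size=n_visits, replace=False,
                        p=(bias / bias.sum()).ravel())
    vr, vc = np.divmod(visits, grid.n_cols)
    effort = effort_kde((vr, vc), grid, valid_mask=ok)
    occ = sim.sample_presences(np.nan_to_num(suitability), effort.weights, grid,
                               n_presences, seed + 1)
    return effort, occ


def niche_recovery_trial(seed: int, n_presences: int = 200, n_background: int = 200,
                         max_trees: int = 800, holdout_fraction: float = 0.2,
                         config: BRTConfig | None = None) -> dict:
    """Fit a BRT on one simulated survey; report held-out AUC and influence.

    The world has 2 informative descriptors (temperature, salinity: the
    species' niche axes) and 3 pure-noise descriptors; presences are drawn
    proportional to suitability x effort and backgrounds proportional to
    effort, the bias-matched design.  A random ``holdout_fraction`` of
    rows is withheld from fitting and scored for AUC.
    """
    grid = Grid(100, 80, 0.0, -56.0, 0.1)
    specs = [
        sim.FieldSpec("temperature", gradient=0.8, intercept=2.0 + 0.8 * 51.0,
                      noise_amp=0.3, corr_length=5),
        sim.FieldSpec("salinity", gradient=0.05, intercept=34.0 + 0.05 * 51.0,
                      noise_amp=0.15, corr_length=5),
        sim.FieldSpec("noise1", noise_amp=1.0, corr_length=4),
        sim.FieldSpec("noise2", noise_amp=1.0, corr_length=6),
        sim.FieldSpec("noise3", noise_amp=1.0, corr_length=8),
    ]
    stack = sim.gen_stack(grid, specs, "present", seed)
    species = sim.VirtualSpecies(
        "recovery", optima={"temperature": 2.0, "salinity": 34.0},
        tolerances=dict(_RECOVERY_TOL),
        weights={"temperature": 1.0, "salinity": 1.0})
    suit = sim.true_suitability(species, stack)
    effort, occ = _survey(stack, grid, suit, n_presences, 300, 0.25, seed + 10000)
    back = sample_background(effort, n_background, seed + 30000,
                             exclude_cells=occ.flat_cells)
    cells = np.concatenate([occ.flat_cells, back])
    y = np.concatenate([np.ones(len(occ)), np.zeros(len(back))])
    X = np.column_stack([stack[n].values.ravel()[cells] for n in stack.names])
    idx = np.random.default_rng(seed + 40000).permutation(len(y))
    n_test = int(round(holdout_fraction * len(y)))
    test, train = idx[:n_test], idx[n_test:]
    cfg = config or BRTConfig(learning_rate=0.01, tree_complexity=2,
                              bag_fraction=0.75, max_trees=max_trees, seed=seed)
    model = fit_brt(X[train], y[train], cfg, feature_names=stack.names)
    scores = model.predict(X[test])
    heldout_auc = auc(scores[y[test] == 1], scores[y[test] == 0])
    infl = relative_influence(model)
    informative = infl["temperature"] + infl["salinity"]
    return {
        "heldout_auc": heldout_auc,
        "informative_influence_pct": informative,
        "noise_influence_pct": 100.0 - informative,
        "influence_sum": sum(infl.values()),
        "influence": infl,
    }


def shift_recovery_trial(seed: int, warming: float = 2.0, n_presences: int = 200,
                         max_trees: int = 500) -> dict:
    """Recover an imposed uniform warming from projected distribution maps.

    A temperature-limited species (gradient 0.8 degC per degree latitude)
    is fitted on the present stack and projected onto a future stack that
    is warmer by ``warming`` everywhere, so suitable habitat must move
    poleward by warming/gradient degrees.  Reported:

    * ``latitude_shift_deg`` — displacement of the suitable-area
      latitudinal centroid (negative = poleward here);
    * ``hull_shift_degC`` — temperature-axis displacement of the occupied
      niche hull for a population held at its present cells (no
      dispersal), which equals the imposed warming;
    * ``instability_future`` vs ``instability_replicate`` — the change
      signal against the between-replicate noise floor.
    """
    grid = Grid(100, 80, 0.0, -56.0, 0.1)
    gradient = 0.8
    specs = [
        sim.FieldSpec("temperature", gradient=gradient, intercept=2.0 + gradient * 51.0,
                      noise_amp=0.3, corr_length=5,
                      period_shift={"future": warming}),
        sim.FieldSpec("salinity", gradient=0.05, intercept=34.0 + 0.05 * 51.0,
                      noise_amp=0.15, corr_length=5),
        sim.FieldSpec("noise1", noise_amp=1.0, corr_length=5),
    ]
    present = sim.gen_stack(grid, specs, "present", seed)
    future = sim.gen_stack(grid, specs, "future", seed)
    species = sim.VirtualSpecies(
        "shifter", optima={"temperature": 2.0}, tolerances={"temperature": 0.5},
        weights={"temperature": 1.0})
    suit = sim.true_suitability(species, present)
    effort, occ = _survey(present, grid, suit, n_presences, 300, 0.25, seed + 10000)

    def fit_replicate(bg_seed):
        back = sample_background(effort, n_presences, bg_seed,
                                 exclude_cells=occ.flat_cells)
        cells = np.concatenate([occ.flat_cells, back])
        y = np.concatenate([np.ones(len(occ)), np.zeros(len(back))])
        X = np.column_stack([present[n].values.ravel()[cells] for n in present.names])
        cfg = BRTConfig(learning_rate=0.01, tree_complexity=2, bag_fraction=0.75,
                        max_trees=max_trees, seed=bg_seed)
        model = fit_brt(X, y, cfg, feature_names=present.names)
        scores = model.predict(X)
        thr = maxsss_threshold(scores[y == 1], scores[y == 0])
        return model, thr

    model, thr = fit_replicate(seed + 30000)
    model2, _ = fit_replicate(seed + 31000)

    map_now = predict_map(model, present)
    map_fut = predict_map(model, future)
    map_now2 = predict_map(model2, present)

    bin_now = binarize(map_now, thr)
    bin_fut = binarize(map_fut, thr)
    lon, lat = grid.cell_centers()

    def lat_centroid(binary):
        if not binary.suitable.any():
            return np.nan
        return float(lat[binary.suitable].mean())

    lat_shift = lat_centroid(bin_fut) - lat_centroid(bin_now)

    # no-dispersal niche hulls: the present suitable cells, with each
    # period's temperature read at those same cells
    box = (grid.south, grid.north, grid.west, grid.east)
    pts_now = occupied_env_points(bin_now, present, ["temperature", "salinity"], box)
    pts_fut = occupied_env_points(bin_now, future, ["temperature", "salinity"], box)
    hull_now = convex_hull_2d(pts_now, ("temperature", "salinity"), "present")
    hull_fut = convex_hull_2d(pts_fut, ("temperature", "salinity"), "future")
    hull_shift = hull_fut.centroid[0] - hull_now.centroid[0]

    inst_future = e_instability(map_fut, map_now, map_now)
    inst_replicate = e_instability(map_now2, map_now, map_now)
    return {
        "warming": warming,
        "expected_lat_shift_deg": -warming / gradient,
        "latitude_shift_deg": lat_shift,
        "poleward": bool(lat_shift < 0),
        "hull_shift_degC": float(hull_shift),
        "instability_future": inst_future,
        "instability_replicate": inst_replicate,
        "suitable_area_present": suitable_area(bin_now),
        "suitable_area_future": suitable_area(bin_fut),
    }
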