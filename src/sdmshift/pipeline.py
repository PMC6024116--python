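"""End-to-end protocol: simulate -> select -> background -> fit -> project
-> indices -> niche -> report.

The protocol mirrors the standard temporal-transfer SDM workflow: fit
replicated presence/background BRT models on the present-day period,
project every replicate onto the past and future environmental stacks,
binarize at the per-replicate MaxSSS threshold, and aggregate suitable
areas, change indices and niche-space hulls over replicates.

Everything stochastic is driven by one global seed: each stage derives
its own seed as ``(seed * 1000003 + crc32(stage name)) mod 2^31``, so
stages are decoupled and a rerun with the same configuration produces a
byte-identical report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import background as bg
from . import simulate as sim
from .brt import BRTConfig, fit_brt, predict_map, relative_influence, select_n_trees
from .evaluate import SuitabilityMap, auc, binarize, maxsss_threshold, suitable_area
from .grid import EnvStack, Grid, ModelingExtent, OccurrenceSet, write_layer, EnvLayer
from .indices import ChangeReport, e_instability, e_occupied, e_overlap, \
    replicate_summary, wilcoxon_paired
from .niche import convex_hull_2d, compare_hulls, occupied_env_points

__all__ = ["RunConfig", "run_protocol", "render_report", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific seed from the global seed (stable hash)."""
    return int((seed * 1000003 + zlib.crc32(stage.encode())) % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full synthetic-protocol run.

    Defaults describe the reference study conditions of the virtual
    world: a 0.1-degree Kerguelen-Plateau-like grid, +2 degC uniform
    warming and -0.3 PSU freshening for the future period, -0.5 degC for
    the past, 200 presence records under northeast-biased survey effort,
    background count equal to presence count and 100 replicate draws.
    """

    seed: int = 42
    periods: dict = field(default_factory=lambda: {
        "past": "1955-1974", "present": "2005-2012", "future": "2050-2099"})
    reference: str = "2005-2012"
    warming: float = 2.0
    freshening: float = -0.3
    past_cooling: float = -0.5
    max_depth: float = 1000.0
    n_presences: int = 200
    n_visits: int = 400
    effort_bias: float = 0.25        # per-degree log-linear visit bias
    n_replicates: int = 100
    kde_bandwidth: float | None = None
    rho_threshold: float = 0.85
    vif_threshold: float = 5.0
    brt: BRTConfig = field(default_factory=lambda: BRTConfig(max_trees=400))
    select_trees_by_cv: bool = False  # CV on the first replicate, reused after
    held_constant: list = field(default_factory=lambda: ["chlorophyll", "ice_cover"])
    top_k_predictors: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "brt" in raw and isinstance(raw["brt"], dict):
            raw = {**raw, "brt": BRTConfig(**raw["brt"])}
        cfg = cls(**raw)
        if cfg.reference not in cfg.periods.values():
            raise ValueError("reference period must be one of the period labels")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _build_world(config: RunConfig):
    """Generate the three-period stacks, mask them, and apply the
    held-constant substitution for layers lacking past/future data."""
    grid = sim.default_grid()
    specs = sim.default_field_specs(warming=config.warming,
                                    freshening=config.freshening,
                                    past_cooling=config.past_cooling)
    world_seed = stage_seed(config.seed, "simulate")
    stacks = {label: sim.gen_stack(grid, specs, label, world_seed)
              for label in config.periods.values()}
    # substitution: layers without past/future data reuse present values
    ref = stacks[config.reference]
    for label, stack in stacks.items():
        if label == config.reference:
            continue
        for name in config.held_constant:
            if name in stack:
                src = ref[name]
                stack.layers[name] = EnvLayer(name, grid, src.values.copy(),
                                              src.mask.copy(), src.kind)
    extent = ModelingExtent(lat_min=grid.south, lat_max=grid.north,
                            lon_min=grid.west, lon_max=grid.east,
                            max_depth=config.max_depth)
    from .grid import mask_to_extent
    stacks = {label: mask_to_extent(s, extent) for label, s in stacks.items()}
    return grid, stacks, extent


def _simulate_survey(config: RunConfig, grid: Grid, present: EnvStack):
    """Visited cells (target-group analog), effort KDE and presences."""
    ok = present.valid_mask()
    lon, lat = grid.cell_centers()
    bias = np.exp(config.effort_bias * ((lat - lat.min()) + (lon - lon.min())))
    bias = np.where(ok, bias, 0.0)
    rng = np.random.default_rng(stage_seed(config.seed, "visits"))
    flat = rng.choice(grid.n_rows * grid.n_cols, size=config.n_visits, replace=False,
                      p=(bias / bias.sum()).ravel())
    vr, vc = np.divmod(flat, grid.n_cols)
    effort = bg.effort_kde((vr, vc), grid, bandwidth=config.kde_bandwidth,
                           valid_mask=ok)
    vs = sim.default_species()
    suit = sim.true_suitability(vs, present)
    occ = sim.sample_presences(np.where(ok, np.nan_to_num(suit), 0.0), effort.weights,
                               grid, config.n_presences,
                               stage_seed(config.seed, "presences"),
                               species=vs.name)
    return effort, occ, vs, suit


def _features_at(stack: EnvStack, names: list[str], flat_cells: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [stack[n].values.ravel()[np.asarray(flat_cells, dtype=int)] for n in names])


def run_protocol(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full protocol and write the report bundle to out_dir.

    Returns the bundle as a dict (the same content as the files).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)

    stage = "simulate"
    try:
        grid, stacks, extent = _build_world(config)
        ref_label = config.reference
        ref_stack = stacks[ref_label]

        stage = "survey"
        effort, occ, vs, true_suit = _simulate_survey(config, grid, ref_stack)

        stage = "select"
        from .select import select_predictors
        selection = select_predictors(ref_stack, config.rho_threshold, config.vif_threshold)
        predictors = selection.kept
        cat_idx = [i for i, n in enumerate(predictors)
                   if ref_stack[n].kind == "categorical"]

        stage = "background"
        reps = bg.make_replicates(occ, effort, n_rep=config.n_replicates,
                                  base_seed=stage_seed(config.seed, "background"))

        stage = "environmental_shift_tests"
        shift_tests = {}
        ok_all = np.ones(grid.shape, dtype=bool)
        for s in stacks.values():
            ok_all &= s.valid_mask()
        rng_w = np.random.default_rng(stage_seed(config.seed, "wilcoxon"))
        cells = np.flatnonzero(ok_all.ravel())
        sub = rng_w.choice(cells, size=min(500, cells.size), replace=False)
        for label in config.periods.values():
            if label == ref_label:
                continue
            for name in predictors:
                if ref_stack[name].kind != "continuous":
                    continue
                a = ref_stack[name].values.ravel()[sub]
                b = stacks[label][name].values.ravel()[sub]
                w, p = wilcoxon_paired(a, b)
                shift_tests[f"{name}: {ref_label} vs {label}"] = {
                    "W": w, "p": p,
                    "note": "cells are spatially autocorrelated; p is descriptive"}

        stage = "fit"
        n_trees_fixed = None
        per_rep = []
        labels_order = list(config.periods.values())
        for r in range(reps.n_replicates):
            pres, back = reps.presence_cells, reps.background_sets[r]
            cells_r = np.concatenate([pres, back])
            y = np.concatenate([np.ones(len(pres)), np.zeros(len(back))])
            X = _features_at(ref_stack, predictors, cells_r)
            cfg_r = BRTConfig(**{**asdict(config.brt),
                                 "seed": stage_seed(config.seed, f"fit-{r}")})
            if config.select_trees_by_cv and n_trees_fixed is None:
                n_trees_fixed, _curve = select_n_trees(X, y, cfg_r, cat_idx)
                logger.info("CV-selected tree count: %d", n_trees_fixed)
            model = fit_brt(X, y, cfg_r, cat_idx, predictors,
                            n_trees=n_trees_fixed)
            scores = model.predict(X)
            rep_auc = auc(scores[y == 1], scores[y == 0])
            thr = maxsss_threshold(scores[y == 1], scores[y == 0])
            maps = {label: predict_map(model, stacks[label], replicate=r)
                    for label in labels_order}
            areas = {label: suitable_area(binarize(maps[label], thr))
                     for label in labels_order}
            eo = {label: e_occupied(maps[label]) for label in labels_order}
            ref_map = maps[ref_label]
            ei, ov = {}, {}
            for label in labels_order:
                if label == ref_label:
                    continue
                ei[label] = e_instability(maps[label], ref_map, ref_map)
                ov[label] = e_overlap(maps[label], ref_map, ref_map)
            per_rep.append({
                "replicate": r, "auc": rep_auc, "maxsss": thr, "areas": areas,
                "e_occupied": eo, "e_instability": ei, "e_overlap": ov,
                "influence": relative_influence(model),
                "maps": maps,
            })

        stage = "aggregate"
        report = ChangeReport(reference=ref_label)
        for label in labels_order:
            report.per_period[label] = {
                "suitable_area": replicate_summary(p["areas"][label] for p in per_rep),
                "e_occupied": replicate_summary(p["e_occupied"][label] for p in per_rep),
            }
        for label in labels_order:
            if label == ref_label:
                continue
            report.comparisons[label] = {
                "e_instability": replicate_summary(p["e_instability"][label] for p in per_rep),
                "e_overlap": replicate_summary(p["e_overlap"][label] for p in per_rep),
            }
        mean_influence = {
            name: float(np.mean([p["influence"][name] for p in per_rep]))
            for name in predictors}
        mean_thr = float(np.mean([p["maxsss"] for p in per_rep]))
        mean_maps = {}
        for label in labels_order:
            stacked = np.stack([p["maps"][label].values for p in per_rep])
            with np.errstate(invalid="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    vals = np.nanmean(stacked, axis=0)
            mean_maps[label] = SuitabilityMap(
                grid=grid, values=vals, mask=per_rep[0]["maps"][label].mask,
                period=label)

        stage = "niche"
        cont = [n for n in predictors if ref_stack[n].kind == "continuous"]
        top = sorted(cont, key=lambda n: -mean_influence[n])[: config.top_k_predictors]
        hulls = {}
        niche_points = {}
        for label in labels_order:
            binary = binarize(mean_maps[label], mean_thr)
            pts = occupied_env_points(binary, stacks[label], top)
            niche_points[label] = pts
            if len(pts):
                hulls[label] = convex_hull_2d(pts[:, :2], tuple(top[:2]), period=label)
        hull_cmp = compare_hulls(hulls) if len(hulls) >= 2 else {}

        stage = "write"
        bundle = {
            "manifest": {
                "config": config.to_dict(), "config_sha256": config.digest(),
                "n_presences": len(occ), "predictors": predictors,
                "categorical_predictors": [predictors[i] for i in cat_idx],
                "n_trees": n_trees_fixed or config.brt.max_trees,
            },
            "selection": selection.to_dict(),
            "evaluation": [
                {k: v for k, v in p.items() if k not in ("maps", "influence")}
                for p in per_rep],
            "influence_mean_pct": mean_influence,
            "maxsss_mean": mean_thr,
            "environmental_shift_tests": shift_tests,
            "change_report": report.to_dict(),
            "niche": {
                "predictor_pair": top[:2],
                "hulls": {label: {
                    "area": h.area, "centroid": list(h.centroid),
                    "n_vertices": h.n_vertices, "degenerate": h.degenerate,
                    "vertices": h.vertices.tolist(),
                } for label, h in hulls.items()},
                "comparisons": hull_cmp,
            },
        }
        _write_bundle(bundle, report, mean_maps, mean_thr, out)
        return bundle
    except Exception as err:
        (out / "FAILED_STAGE.txt").write_text(f"{stage}: {err}\n")
        raise RuntimeError(f"protocol failed at stage {stage!r}: {err}") from err


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_bundle(bundle: dict, report: ChangeReport, mean_maps: dict,
                  mean_thr: float, out: Path) -> None:
    (out / "report.json").write_text(
        json.dumps(bundle, sort_keys=True, indent=1, default=_json_default))
    (out / "change_report.txt").write_text(report.render())
    for label, smap in mean_maps.items():
        safe = label.replace("/", "-")
        layer = EnvLayer(f"suitability_{safe}", smap.grid,
                         np.nan_to_num(smap.values), smap.mask)
        write_layer(layer, out / "maps" / f"mean_suitability_{safe}.asc")
        binary = binarize(smap, mean_thr)
        blayer = EnvLayer(f"binary_{safe}", smap.grid,
                          binary.suitable.astype(float), binary.mask)
        write_layer(blayer, out / "maps" / f"binary_{safe}.asc")


def render_report(bundle: dict) -> str:
    """Human-readable run summary: evaluation, indices, influences, niche."""
    lines = ["run summary", "===========", ""]
    ev = bundle.get("evaluation", [])
    if ev:
        aucs = [e["auc"] for e in ev]
        lines.append(f"replicates: {len(ev)};  AUC mean {np.mean(aucs):.3f}"
                     f" (min {min(aucs):.3f}, max {max(aucs):.3f});"
                     f"  MaxSSS mean {bundle.get('maxsss_mean', float('nan')):.3f}")
        lines.append("")
    cr = bundle.get("change_report")
    if cr:
        rep = ChangeReport(reference=cr["reference"])
        rep.per_period = {k: {m: tuple(v) for m, v in d.items()}
                          for k, d in cr["per_period"].items()}
        rep.comparisons = {k: {m: tuple(v) for m, v in d.items()}
                           for k, d in cr["comparisons"].items()}
        lines.append(rep.render())
    infl = bundle.get("influence_mean_pct")
    if infl:
        lines.append("relative influence (%, replicate mean):")
        for name, pct in sorted(infl.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {name:>16}: {pct:6.1f}")
        lines.append("")
    niche = bundle.get("niche")
    if niche and niche.get("hulls"):
        pair = niche.get("predictor_pair", [])
        lines.append(f"niche hulls on ({', '.join(pair)}):")
        for label, h in niche["hulls"].items():
            lines.append(f"  {label:>12}: area {h['area']:.3f}, centroid "
                         f"({h['centroid'][0]:.3f}, {h['centroid'][1]:.3f})")
        for key, cmp_ in niche.get("comparisons", {}).items():
            dx, dy = cmp_["displacement"]
            lines.append(f"  {key}: centroid moved ({dx:+.3f}, {dy:+.3f}), "
                         f"area ratio {cmp_['area_ratio']:.2f}")
    return "\n".join(lines) + "\n"
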