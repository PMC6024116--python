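"""Virtual-species world generator.

Builds multi-period environmental stacks with known structure so that every
downstream stage of the modelling pipeline can be checked against ground
truth:

* continuous descriptors = latitudinal gradient + spatially correlated
  Gaussian noise + a per-period additive shift (warming / freshening
  between periods);
* optional collinear descriptors constructed as weighted sums of parents
  plus Gaussian noise, to exercise the collinearity filters;
* a categorical "geomorphology" descriptor obtained by thresholding a
  latent continuous field into three codes;
* a virtual species with a product-of-Gaussians niche over named
  descriptors, giving a known suitability surface, optimum and tolerance;
* spatially biased presence sampling, with detection probability
  proportional to suitability x survey effort.

Shifting a gradient field by a uniform +delta moves every isotherm by
exactly delta/slope degrees of latitude, which is the ground truth used by
the range-shift recovery checks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .grid import EnvLayer, EnvStack, Grid, OccurrenceSet

__all__ = [
    "FieldSpec",
    "VirtualSpecies",
    "gen_stack",
    "true_suitability",
    "sample_presences",
    "default_field_specs",
    "default_species",
    "default_grid",
]


@dataclass(frozen=True)
class FieldSpec:
    """Recipe for one synthetic environmental descriptor.

    ``gradient`` is the change in field units per degree of latitude
    northward; ``noise_amp``/``corr_length`` control a moving-average
    smoothed Gaussian noise field (correlation length in cells);
    ``period_shift`` maps period label -> additive offset.  A collinear
    child sets ``parents``/``weights`` and is built as the weighted parent
    sum plus N(0, collinear_noise_sd) noise, ignoring the gradient/noise
    fields.  ``categorical_codes`` > 0 turns the (latent) field into that
    many integer codes by quantile thresholding.
    """

    name: str
    gradient: float = 0.0
    intercept: float = 0.0
    noise_amp: float = 0.0
    corr_length: int = 1
    period_shift: dict[str, float] = field(default_factory=dict)
    parents: tuple[str, ...] = ()
    weights: tuple[float, ...] = ()
    collinear_noise_sd: float = 0.0
    categorical_codes: int = 0

    def __post_init__(self) -> None:
        if self.corr_length < 1:
            raise ValueError("correlation length must be >= 1 cell")
        if len(self.parents) != len(self.weights):
            raise ValueError("parents and weights must have equal length")


@dataclass(frozen=True)
class VirtualSpecies:
    """Ground-truth niche: product of Gaussian responses over descriptors.

    Suitability at a cell with descriptor values x_j is

        s = prod_j exp(-(x_j - opt_j)^2 / (2 tol_j^2)) ** w_j

    rescaled so its maximum over unmasked cells is 1.
    """

    name: str
    optima: dict[str, float]
    tolerances: dict[str, float]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.tolerances) or set(self.optima) != set(self.weights):
            raise ValueError("optima, tolerances and weights must share keys")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one predictor weight must be positive")
        if any(t <= 0 for t in self.tolerances.values()):
            raise ValueError("tolerances must be positive")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  corr_length: int) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed by a moving average window."""
    raw = rng.standard_normal(shape)
    if corr_length <= 1:
        return raw
    k = corr_length
    kernel = np.ones(k) / k
    pad = k  # reflect-pad so edges keep comparable variance
    sm = np.pad(raw, pad, mode="reflect")
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, sm)
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, sm)
    sm = sm[pad:-pad, pad:-pad]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def gen_stack(grid: Grid, specs: list[FieldSpec], period: str, seed: int) -> EnvStack:
    """Generate one period's environmental stack from field recipes.

    The noise field of each descriptor is seeded by (seed, descriptor
    name) only, so two periods generated with the same seed differ exactly
    by their period shifts — between-period change is fully controlled.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate field names in specs")
    stack = EnvStack(grid, period)
    lon, lat = grid.cell_centers()
    no_mask = np.zeros(grid.shape, dtype=bool)
    for spec in specs:
        if spec.parents:
            values = np.zeros(grid.shape)
            for parent, w in zip(spec.parents, spec.weights):
                if parent not in stack:
                    raise ValueError(f"collinear field {spec.name!r}: unknown parent {parent!r}")
                values = values + w * stack[parent].values
            if spec.collinear_noise_sd > 0:
                child_rng = np.random.default_rng(
                    [seed, zlib.crc32(spec.name.encode()) % (2**31)])
                values = values + spec.collinear_noise_sd * child_rng.standard_normal(grid.shape)
        else:
            values = spec.intercept + spec.gradient * lat
            if spec.noise_amp > 0:
                field_rng = np.random.default_rng(
                    [seed, zlib.crc32(spec.name.encode()) % (2**31)])
                values = values + spec.noise_amp * _smooth_noise(
                    field_rng, grid.shape, spec.corr_length)
        values = values + spec.period_shift.get(period, 0.0)
        kind = "continuous"
        if spec.categorical_codes > 0:
            edges = np.quantile(values, np.linspace(0, 1, spec.categorical_codes + 1)[1:-1])
            values = np.digitize(values, edges).astype(float)
            kind = "categorical"
        stack.add(EnvLayer(spec.name, grid, values, no_mask.copy(), kind))
    return stack


def true_suitability(vs: VirtualSpecies, stack: EnvStack) -> np.ndarray:
    """Ground-truth suitability surface in [0, 1], max 1 over unmasked cells.

    Returns an array on the stack grid; masked cells are NaN.
    """
    for name in vs.optima:
        if name not in stack:
            raise ValueError(f"virtual species uses missing predictor {name!r}")
    log_s = np.zeros(stack.grid.shape)
    for name, opt in vs.optima.items():
        tol = vs.tolerances[name]
        w = vs.weights[name]
        x = stack[name].values
        log_s = log_s - w * (x - opt) ** 2 / (2.0 * tol**2)
    ok = stack.valid_mask()
    if not np.any(ok):
        raise ValueError("no unmasked cells in stack")
    log_s = log_s - log_s[ok].max()
    s = np.exp(log_s)
    s[~ok] = np.nan
    return s


def sample_presences(suitability: np.ndarray, effort: np.ndarray, grid: Grid,
                     n: int, seed: int, species: str = "virtual") -> OccurrenceSet:
    """Draw n presence cells without replacement, P(cell) ∝ suitability x effort.

    Emulates detection bias: a cell is recorded only if it is both suitable
    and surveyed.  Records are placed at cell centers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.asarray(suitability, dtype=float).ravel() * np.asarray(effort, dtype=float).ravel()
    w = np.where(np.isfinite(w), w, 0.0)
    w = np.clip(w, 0.0, None)
    positive = np.flatnonzero(w > 0)
    if positive.size < n:
        raise ValueError(
            f"only {positive.size} cells have positive suitability x effort; need {n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(positive, size=n, replace=False, p=w[positive] / w[positive].sum())
    rows, cols = np.divmod(chosen, grid.n_cols)
    res = grid.resolution
    lon = grid.west + (cols + 0.5) * res
    lat = grid.north - (rows + 0.5) * res
    return OccurrenceSet(species=species, grid=grid, lon=lon, lat=lat, rows=rows, cols=cols)


# ---------------------------------------------------------------------------
# default study conditions


def default_grid() -> Grid:
    """0.1-degree grid over a Kerguelen-Plateau-like box (-56..-46S, 63..81E)."""
    return Grid(n_rows=100, n_cols=180, west=63.0, south=-56.0, resolution=0.1)


def default_field_specs(warming: float = 2.0, freshening: float = -0.3,
                        past_cooling: float = -0.5) -> list[FieldSpec]:
    """Descriptor recipes for the three-period virtual world.

    Temperature warms northward (0.8 degC per degree latitude) and is
    shifted by ``past_cooling`` for the past period and ``warming`` for the
    future; salinity freshens in the future.  Depth, geomorphology and the
    noise descriptors are held constant across periods, and one exactly
    collinear and one R^2≈0.9 descriptor are planted for the collinearity
    filters.
    """
    periods = {"past": "1955-1974", "present": "2005-2012", "future": "2050-2099"}
    # Noise amplitudes are balanced against the shared latitudinal gradient
    # so that distinct descriptors stay below the |rho| = 0.85 / VIF = 5
    # filters while the two planted layers (exact copy; mixed layer with
    # R^2 ~ 0.9, VIF ~ 10) are reliably removed.
    return [
        FieldSpec("temperature", gradient=0.8, intercept=2.0 + 0.8 * 51.0,
                  noise_amp=0.3, corr_length=5,
                  period_shift={periods["past"]: past_cooling,
                                periods["future"]: warming}),
        FieldSpec("salinity", gradient=0.05, intercept=34.0 + 0.05 * 51.0,
                  noise_amp=0.15, corr_length=5,
                  period_shift={periods["future"]: freshening}),
        FieldSpec("depth", gradient=-20.0, intercept=600.0 - 20.0 * 51.0,
                  noise_amp=200.0, corr_length=8),
        FieldSpec("chlorophyll", gradient=0.0, intercept=1.0,
                  noise_amp=0.4, corr_length=6),
        FieldSpec("ice_cover", gradient=-0.02, intercept=0.2 - 0.02 * 51.0,
                  noise_amp=0.15, corr_length=6),
        # planted collinear descriptors: an exact duplicate (infinite VIF)
        # and a weighted temperature+chlorophyll mix whose noise sd gives
        # R^2 ~ 0.9 against its parents (VIF ~ 10) but pairwise rho ~ 0.67
        FieldSpec("temp_copy", parents=("temperature",), weights=(1.0,)),
        FieldSpec("temp_chl_mix", parents=("temperature", "chlorophyll"),
                  weights=(0.43, 2.5), collinear_noise_sd=0.47),
        # categorical geomorphology from a latent smooth field
        FieldSpec("geomorphology", gradient=0.3, noise_amp=1.0, corr_length=10,
                  categorical_codes=3),
    ]


def default_species() -> VirtualSpecies:
    """Temperature/salinity-limited virtual echinoid-like species."""
    return VirtualSpecies(
        name="virtual_urchin",
        optima={"temperature": 2.0, "salinity": 34.0},
        tolerances={"temperature": 1.2, "salinity": 0.25},
        weights={"temperature": 1.0, "salinity": 1.0},
    )
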