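"""Fully synthetic island dataset with known ground truth.

Everything downstream of data acquisition — predictor screening, MaxEnt
fitting, ensemble selection, occupancy-area delineation and climate-scenario
projection — can be exercised against this generator because the suitability
surface that produced the presences is known exactly.

The island is a volcanic cone plus ridged noise; "climate" layers are affine
functions of elevation with spatially correlated noise (mimicking bioclim-style
summaries such as isothermality or precipitation seasonality, which on steep
oceanic islands are strongly elevation-driven); land cover is an
elevation-banded categorical grid at 3× coarser resolution; presences are
drawn from a logistic-linear suitability in the standardised climate layers.
Future climates are deterministic per-scenario shifts of the present layers
with land cover and topography held constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import EnvStack, Grid, OccurrenceSet

__all__ = [
    "SyntheticIslandConfig",
    "SyntheticTruth",
    "generate_dem",
    "generate_climate_layers",
    "generate_landcover",
    "true_suitability",
    "sample_presences",
    "perturb_future",
    "default_shift_table",
    "simulate_island",
    "DEFAULT_CROSSWALK",
    "LANDCOVER_BANDS",
    "SSP_LABELS",
    "GCM_LABELS",
]

# Fraction of the shorter grid side used as the cone radius; the remainder is
# sea, guaranteeing a water margin around the island.
_CONE_RADIUS_FRACTION = 0.42
# DEM ridged-noise amplitude, in metres per unit of config.noise_sd.
_DEM_NOISE_SCALE = 10.0

# Per-layer intercepts/gradients of the elevation-driven climate signal, cycled
# when more layers are requested.  Gradients are sized so each layer spans
# roughly +-20 units over a 1500 m relief, keeping one noise_sd comparable
# across layers.
_CLIMATE_INTERCEPTS = (50.0, 400.0, 30.0, 90.0, 15.0, 200.0, 70.0, 120.0)
_CLIMATE_GRADIENTS = (-0.010, 0.012, 0.015, -0.013, 0.011, -0.009, 0.014, -0.012)

SSP_LABELS = ("ssp126", "ssp370", "ssp585")
GCM_LABELS = ("IPSL", "GFDL", "MPI", "MRI", "UKESM1")

# Elevation bands (metres, lower edge inclusive) -> land-cover class code.
LANDCOVER_BANDS = (
    (0.0, 60),     # coastal bare ground
    (80.0, 50),    # low settlement belt
    (250.0, 30),   # cropland terraces
    (500.0, 40),   # grassland
    (800.0, 20),   # shrub / scrub
    (1200.0, 10),  # summit forest
)

# Class code -> plant-functional-type fractions (tree, shrub, crop, grass,
# urban, bare); rows sum to <= 1, residual = other/water.
DEFAULT_CROSSWALK = {
    10: {"tree": 0.80, "shrub": 0.15, "crop": 0.0, "grass": 0.05, "urban": 0.0, "bare": 0.0},
    20: {"tree": 0.10, "shrub": 0.70, "crop": 0.0, "grass": 0.15, "urban": 0.0, "bare": 0.05},
    30: {"tree": 0.05, "shrub": 0.05, "crop": 0.70, "grass": 0.15, "urban": 0.05, "bare": 0.0},
    40: {"tree": 0.05, "shrub": 0.10, "crop": 0.10, "grass": 0.70, "urban": 0.0, "bare": 0.05},
    50: {"tree": 0.05, "shrub": 0.05, "crop": 0.15, "grass": 0.10, "urban": 0.60, "bare": 0.05},
    60: {"tree": 0.0, "shrub": 0.10, "crop": 0.0, "grass": 0.10, "urban": 0.05, "bare": 0.75},
}


@dataclass(frozen=True)
class SyntheticIslandConfig:
    """Study conditions for one synthetic island.

    ``true_coefficients`` is (intercept, then one coefficient per climate
    layer) on the standardised-layer scale; it defines the logistic ground
    truth that presences are sampled from.
    """

    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 100.0
    peak_elevation: float = 1500.0
    n_climate_layers: int = 4
    noise_sd: float = 1.0
    smoothing_radius: int = 3
    true_coefficients: tuple[float, ...] = (-3.0, 3.0, -2.0, 4.0, 1.6)
    n_presence: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError("grid must be at least 16 cells per side")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.n_presence < 20:
            raise ValueError("n_presence must be >= 20")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_climate_layers < 1:
            raise ValueError("need at least one climate layer")
        if len(self.true_coefficients) != self.n_climate_layers + 1:
            raise ValueError(
                "true_coefficients must have length n_climate_layers + 1 "
                f"(intercept first); got {len(self.true_coefficients)} for "
                f"{self.n_climate_layers} layers"
            )

    def climate_names(self) -> list[str]:
        return [f"clim{k + 1:02d}" for k in range(self.n_climate_layers)]

    def grid(self) -> Grid:
        return Grid(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
            origin=(0.0, self.n_rows * self.cell_size),
            crs_id="local-metric",
        )


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated island."""

    suitability: np.ndarray
    coefficients: tuple[float, ...]
    presence_points: OccurrenceSet

    def write_sidecar(self, path) -> None:
        lines = ["# synthetic-island ground truth"]
        lines.append(
            "coefficients=" + ",".join(repr(float(c)) for c in self.coefficients)
        )
        lines.append(f"n_presence={len(self.presence_points)}")
        for k, v in self.presence_points.meta.items():
            lines.append(f"{k}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def read_sidecar(path) -> dict:
        out: dict = {}
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            if key == "coefficients":
                out[key] = tuple(float(v) for v in val.split(","))
            else:
                try:
                    out[key] = int(val)
                except ValueError:
                    out[key] = val
        return out


# ----------------------------------------------------------------------
# generators


def _smoothed_noise(rng: np.random.Generator, shape, radius: int) -> np.ndarray:
    """White noise averaged over a (2r+1)^2 uniform kernel, rescaled so the
    per-cell standard deviation stays ~1 (averaging k iid cells shrinks the
    sd by sqrt(k))."""
    z = rng.standard_normal(shape)
    if radius > 0:
        size = 2 * radius + 1
        z = ndimage.uniform_filter(z, size=size, mode="reflect") * size
    return z


def generate_dem(config: SyntheticIslandConfig) -> tuple[np.ndarray, Grid]:
    """Cone-plus-ridged-noise elevation; cells at or below sea level are NaN.

    Land is reduced to its largest 4-connected component so the island is a
    single landmass.  With ``noise_sd == 0`` the surface is a pure radial cone.
    """
    grid = config.grid()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rows = np.arange(config.n_rows)[:, None]
    cols = np.arange(config.n_cols)[None, :]
    cr = (config.n_rows - 1) / 2.0
    cc = (config.n_cols - 1) / 2.0
    r = np.hypot(rows - cr, cols - cc) * config.cell_size
    radius = _CONE_RADIUS_FRACTION * min(config.n_rows, config.n_cols) * config.cell_size
    base = config.peak_elevation * (1.0 - r / radius)
    if config.noise_sd > 0:
        z = _smoothed_noise(rng, grid.shape, config.smoothing_radius)
        # ridged term: crests along the zero contours of the noise field
        ridged = (1.0 - np.abs(z) / max(1.0, np.abs(z).max())) - 0.5
        elev = base + 2.0 * _DEM_NOISE_SCALE * config.noise_sd * ridged
    else:
        elev = base
    land = elev > 0
    labels, n_comp = ndimage.label(land)  # default structure = 4-connectivity
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        land = labels == (int(np.argmax(sizes)) + 1)
    dem = np.where(land, elev, np.nan)
    return dem, grid


def generate_climate_layers(
    dem: np.ndarray, grid: Grid, config: SyntheticIslandConfig
) -> EnvStack:
    """Bioclim-like layers: affine in elevation plus spatially correlated noise.

    Layer ``k`` is ``a_k + b_k * elevation + eps`` where ``eps`` is white noise
    of sd ``noise_sd`` smoothed with a uniform kernel of ``smoothing_radius``
    cells (variance restored after smoothing).  Nodata follows the DEM.
    """
    land = np.isfinite(dem)
    layers: dict[str, np.ndarray] = {}
    for k, name in enumerate(config.climate_names()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, k]))
        a = _CLIMATE_INTERCEPTS[k % len(_CLIMATE_INTERCEPTS)]
        b = _CLIMATE_GRADIENTS[k % len(_CLIMATE_GRADIENTS)]
        layer = a + b * np.where(land, dem, 0.0)
        if config.noise_sd > 0:
            layer = layer + config.noise_sd * _smoothed_noise(
                rng, grid.shape, config.smoothing_radius
            )
        layers[name] = np.where(land, layer, np.nan)
    return EnvStack(grid, layers)


def generate_landcover(
    dem: np.ndarray, grid: Grid, config: SyntheticIslandConfig
) -> tuple[np.ndarray, Grid]:
    """Elevation-banded categorical land cover on a 3x coarser grid.

    Each coarse cell aggregates a 3x3 block of the DEM (mean over land cells;
    sea if the block has no land) and takes the class of the band containing
    that mean elevation.
    """
    factor = 3
    coarse = grid.aggregate(factor)
    nr, nc = coarse.shape
    block = dem[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
    block = block.transpose(0, 2, 1, 3).reshape(nr, nc, factor * factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        mean_elev = np.nanmean(block, axis=2)
    out = np.full(coarse.shape, np.nan)
    land = np.isfinite(mean_elev)
    codes = classify_elevation(mean_elev[land])
    out[land] = codes
    return out, coarse


def classify_elevation(elev: np.ndarray) -> np.ndarray:
    """Band an elevation array into land-cover class codes."""
    elev = np.asarray(elev, dtype=float)
    codes = np.full(elev.shape, LANDCOVER_BANDS[0][1], dtype=float)
    for lower, code in LANDCOVER_BANDS:
        codes = np.where(elev >= lower, code, codes)
    return codes


def standardise_layers(stack: EnvStack) -> EnvStack:
    """Z-score every layer over the common land mask."""
    land = stack.land_mask()
    out = {}
    for name in stack.names:
        arr = stack[name]
        mu = np.nanmean(arr[land])
        sd = np.nanstd(arr[land])
        out[name] = (arr - mu) / sd if sd > 0 else arr - mu
    return EnvStack(stack.grid, out)


def true_suitability(stack: EnvStack, coefficients) -> np.ndarray:
    """Logistic-linear ground-truth suitability in (0, 1) over land cells.

    ``coefficients`` = (intercept, one slope per layer) on the standardised
    scale; layers are standardised internally over the land mask.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) != len(stack) + 1:
        raise ValueError(
            f"expected {len(stack) + 1} coefficients (intercept + "
            f"{len(stack)} layers), got {len(coefficients)}"
        )
    std = standardise_layers(stack)
    eta = np.full(stack.grid.shape, coefficients[0])
    for coef, name in zip(coefficients[1:], std.names):
        eta = eta + coef * std[name]
    land = stack.land_mask()
    with np.errstate(over="ignore"):
        suit = 1.0 / (1.0 + np.exp(-eta))
    return np.where(land, suit, np.nan)


def sample_presences(
    suitability: np.ndarray, grid: Grid, n: int, seed: int, dedupe: bool = True
) -> OccurrenceSet:
    """Draw presences at land-cell centres with probability ∝ suitability.

    Draws ``n`` cells with replacement, then (by default) deduplicates to one
    record per cell, preserving draw order.  Both counts are recorded in
    ``meta`` (``n_drawn``, ``n_unique``); the raw drawn flat-cell indices stay
    available as ``meta['drawn_cells']``.  Sources alternate between
    ``monitoring`` and ``aggregator`` tags to mimic a mixed-provenance dataset.
    """
    rng = np.random.default_rng(seed)
    flat = np.flatnonzero(np.nan_to_num(suitability.ravel(), nan=0.0) > 0)
    if flat.size == 0 or (dedupe and n > flat.size):
        # with deduplication the requested count can never be reached when it
        # exceeds the positive-suitability cells; plain replacement sampling
        # has no such cap
        raise ValueError(
            f"cannot draw {n} presences: only {flat.size} land cells with "
            "positive suitability"
        )
    p = suitability.ravel()[flat]
    p = p / p.sum()
    draws = rng.choice(flat, size=n, replace=True, p=p)
    if dedupe:
        _, first = np.unique(draws, return_index=True)
        cells = draws[np.sort(first)]
    else:
        cells = draws
    rows, cols = np.unravel_index(cells, grid.shape)
    x, y = grid.cell_centre(rows, cols)
    source = np.where(rng.random(len(cells)) < 0.5, "monitoring", "aggregator")
    occ = OccurrenceSet.from_arrays(x, y, source=source.astype(object), date="2015-01-01")
    occ.meta.update(
        n_drawn=int(n), n_unique=int(np.unique(draws).size), drawn_cells=draws
    )
    return occ


# ----------------------------------------------------------------------
# future scenarios


def default_shift_table(
    climate_names: list[str], noise_sd: float = 0.0
) -> dict[tuple[str, str], dict[str, tuple[str, float]]]:
    """Deterministic per-scenario climate shifts for 3 SSPs x 5 GCMs.

    Temperature-like layers (positive elevation gradient in the generator
    cycle, i.e. even-indexed names clim02, clim04, ...) get additive shifts;
    precipitation-like layers get multiplicative drying.  Shift size scales
    with SSP severity and GCM climate sensitivity, so scenario divergence is
    exact and test-friendly.  ``noise_sd`` > 0 adds a seeded per-layer jitter
    at :func:`perturb_future` time.
    """
    severity = {"ssp126": 1.0, "ssp370": 2.2, "ssp585": 3.0}
    sensitivity = {"IPSL": 1.8, "GFDL": 0.35, "MPI": 1.0, "MRI": 0.7, "UKESM1": 1.5}
    table: dict[tuple[str, str], dict[str, tuple[str, float]]] = {}
    for ssp in SSP_LABELS:
        for gcm in GCM_LABELS:
            scale = severity[ssp] * sensitivity[gcm]
            shifts: dict[str, tuple[str, float]] = {}
            for k, name in enumerate(climate_names):
                if _CLIMATE_GRADIENTS[k % len(_CLIMATE_GRADIENTS)] > 0:
                    shifts[name] = ("add", 1.2 * scale)
                else:
                    shifts[name] = ("mul", max(0.05, 1.0 - 0.05 * scale))
            table[(ssp, gcm)] = shifts
    return table


def perturb_future(
    stack: EnvStack,
    ssp_label: str,
    gcm_label: str,
    shift_table: dict[tuple[str, str], dict[str, tuple[str, float]]],
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> EnvStack:
    """Apply one scenario's climate shifts; non-climate layers untouched.

    Shift entries are ``("add", delta)`` or ``("mul", factor)`` per layer
    name.  Layers absent from the shift row pass through unchanged (land
    cover and topography stay constant across scenarios).
    """
    key = (ssp_label, gcm_label)
    if key not in shift_table:
        known = sorted({k[0] for k in shift_table}), sorted({k[1] for k in shift_table})
        raise KeyError(
            f"unknown scenario {key}; known SSPs {known[0]}, GCMs {known[1]}"
        )
    shifts = shift_table[key]
    rng = np.random.default_rng(seed) if seed is not None else None
    out = stack.copy()
    for name in stack.names:
        if name not in shifts:
            continue
        mode, value = shifts[name]
        arr = out[name]
        if mode == "add":
            arr = arr + value
        elif mode == "mul":
            arr = arr * value
        else:
            raise ValueError(f"unknown shift mode {mode!r} for layer {name!r}")
        if noise_sd > 0 and rng is not None:
            arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
        out[name] = arr
    return out


# ----------------------------------------------------------------------
# one-call simulation


@dataclass
class SyntheticIsland:
    """Bundle returned by :func:`simulate_island`."""

    config: SyntheticIslandConfig
    grid: Grid
    dem: np.ndarray
    climate: EnvStack
    landcover: np.ndarray
    landcover_grid: Grid
    truth: SyntheticTruth


def simulate_island(config: SyntheticIslandConfig) -> SyntheticIsland:
    """Generate DEM, climate, land cover, ground truth and presences."""
    dem, grid = generate_dem(config)
    climate = generate_climate_layers(dem, grid, config)
    landcover, lc_grid = generate_landcover(dem, grid, config)
    suit = true_suitability(climate, config.true_coefficients)
    occ = sample_presences(
        suit, grid, config.n_presence, seed=np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % (2**31)
    )
    truth = SyntheticTruth(
        suitability=suit,
        coefficients=tuple(config.true_coefficients),
        presence_points=occ,
    )
    truth.presence_points.meta["seed"] = config.seed
    return SyntheticIsland(
        config=config,
        grid=grid,
        dem=dem,
        climate=climate,
        landcover=landcover,
        landcover_grid=lc_grid,
        truth=truth,
    )
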