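"""Predictor preparation and screening.

Covers the standard SDM preprocessing chain: bilinear resampling between
grids, Horn terrain derivatives from a DEM, categorical land cover to
plant-functional-type fractions, collinearity/VIF predictor selection, and a
Mantel correlogram as a spatial-autocorrelation diagnostic on occurrences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .grid import EnvStack, Grid, OccurrenceSet

__all__ = [
    "bilinear_resample",
    "terrain_derivatives",
    "landcover_to_pft",
    "vif_correlation_select",
    "mantel_correlogram",
    "filter_records",
    "MantelResult",
    "VarSelectionReport",
    "PFT_NAMES",
]

log = logging.getLogger("maxampo")

PFT_NAMES = ("tree", "shrub", "crop", "grass", "urban", "bare")

# Diagnostic cutoff on per-class Mantel r above which a warning is emitted;
# the test is a gate that warns, it never thins the data itself.
MANTEL_WARN_R = 0.15


# ----------------------------------------------------------------------
# resampling


def bilinear_resample(
    layer: np.ndarray, source_grid: Grid, target_grid: Grid
) -> np.ndarray:
    """Resample a layer onto a new grid by cell-centre bilinear interpolation.

    Each target cell-centre value interpolates the 4 surrounding source cell
    centres; outside the source centre lattice the edge value is extended
    (clamped-edge).  If any of the 4 contributing neighbours is nodata the
    output cell is nodata.
    """
    if (
        source_grid.x_max <= target_grid.x_min
        or target_grid.x_max <= source_grid.x_min
        or source_grid.y_max <= target_grid.y_min
        or target_grid.y_max <= source_grid.y_min
    ):
        raise ValueError("source and target extents are disjoint")
    layer = np.asarray(layer, dtype=float)
    xt, yt = target_grid.cell_centres()
    # fractional position in source cell-centre coordinates
    gx = (xt - source_grid.x_min) / source_grid.cell_size - 0.5
    gy = (source_grid.y_max - yt) / source_grid.cell_size - 0.5
    gx = np.clip(gx, 0.0, source_grid.n_cols - 1.0)
    gy = np.clip(gy, 0.0, source_grid.n_rows - 1.0)
    c0 = np.clip(np.floor(gx).astype(int), 0, source_grid.n_cols - 2) if source_grid.n_cols > 1 else np.zeros(gx.shape, int)
    r0 = np.clip(np.floor(gy).astype(int), 0, source_grid.n_rows - 2) if source_grid.n_rows > 1 else np.zeros(gy.shape, int)
    fx = (gx - c0)[None, :]
    fy = (gy - r0)[:, None]
    c0 = c0[None, :]
    r0 = r0[:, None]
    c1 = np.minimum(c0 + 1, source_grid.n_cols - 1)
    r1 = np.minimum(r0 + 1, source_grid.n_rows - 1)
    v00 = layer[r0, c0]
    v01 = layer[r0, c1]
    v10 = layer[r1, c0]
    v11 = layer[r1, c1]
    out = (
        v00 * (1 - fy) * (1 - fx)
        + v01 * (1 - fy) * fx
        + v10 * fy * (1 - fx)
        + v11 * fy * fx
    )
    bad = ~(np.isfinite(v00) & np.isfinite(v01) & np.isfinite(v10) & np.isfinite(v11))
    out = np.asarray(out, dtype=float)
    out[bad] = np.nan
    return out


# ----------------------------------------------------------------------
# terrain


def terrain_derivatives(dem: np.ndarray, grid: Grid) -> EnvStack:
    """Elevation, slope, aspect and roughness from a metric DEM.

    Slope (degrees) and aspect (degrees clockwise from north, 0-360, pointing
    *down*-slope) use Horn's 3x3 weighted finite differences; roughness is the
    3x3 max-min elevation range.  Border cells and any window touching nodata
    are nodata.  Aspect on flat cells is nodata — a zero would alias "north".
    """
    if grid.is_geographic:
        raise ValueError(
            "terrain derivatives need a projected metric grid; reproject the "
            f"DEM first (got crs_id={grid.crs_id!r})"
        )
    dem = np.asarray(dem, dtype=float)
    nr, nc = dem.shape
    slope = np.full_like(dem, np.nan)
    aspect = np.full_like(dem, np.nan)
    rough = np.full_like(dem, np.nan)
    if nr >= 3 and nc >= 3:
        # 3x3 neighbourhood views around interior cells:
        #   a b c
        #   d e f
        #   g h i
        a = dem[:-2, :-2]; b = dem[:-2, 1:-1]; c = dem[:-2, 2:]
        d = dem[1:-1, :-2]; e = dem[1:-1, 1:-1]; f = dem[1:-1, 2:]
        g = dem[2:, :-2]; h = dem[2:, 1:-1]; i = dem[2:, 2:]
        window = np.stack([a, b, c, d, e, f, g, h, i])
        ok = np.all(np.isfinite(window), axis=0)
        s = grid.cell_size
        dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * s)
        # +y is north (row index decreases northwards)
        dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * s)
        grad = np.hypot(dzdx, dzdy)
        sl = np.degrees(np.arctan(grad))
        # azimuth of the downslope vector -(dzdx, dzdy), clockwise from north
        asp = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
        asp = np.where(grad > 0, asp, np.nan)
        rg = window.max(axis=0) - window.min(axis=0)
        slope[1:-1, 1:-1] = np.where(ok, sl, np.nan)
        aspect[1:-1, 1:-1] = np.where(ok, asp, np.nan)
        rough[1:-1, 1:-1] = np.where(ok, rg, np.nan)
    return EnvStack(
        grid,
        {"elevation": dem.copy(), "slope": slope, "aspect": aspect, "roughness": rough},
    )


# ----------------------------------------------------------------------
# land cover -> plant functional types


def landcover_to_pft(
    categorical: np.ndarray, grid: Grid, crosswalk: dict[int, dict[str, float]]
) -> EnvStack:
    """Expand categorical land cover into fractional PFT layers.

    ``crosswalk`` maps each class code to fractions for the six plant
    functional types (tree, shrub, crop, grass, urban, bare); per cell the six
    fractions sum to <= 1, the residual being water/other.
    """
    categorical = np.asarray(categorical, dtype=float)
    present = np.unique(categorical[np.isfinite(categorical)]).astype(int)
    unknown = [int(c) for c in present if int(c) not in crosswalk]
    if unknown:
        raise ValueError(f"land-cover codes missing from crosswalk: {unknown}")
    layers = {name: np.full(categorical.shape, np.nan) for name in PFT_NAMES}
    for code in present:
        sel = categorical == code
        row = crosswalk[int(code)]
        for name in PFT_NAMES:
            layers[name][sel] = float(row.get(name, 0.0))
    return EnvStack(grid, layers)


# ----------------------------------------------------------------------
# predictor selection


@dataclass
class VarSelectionReport:
    """Audit trail of the pairwise-correlation + VIF screening."""

    pairwise_r: pd.DataFrame
    vif: dict[str, float]
    kept: list[str]
    dropped: list[tuple[str, str]]  # (name, reason)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"variable": n, "status": "kept", "reason": ""} for n in self.kept]
        rows += [
            {"variable": n, "status": "dropped", "reason": why}
            for n, why in self.dropped
        ]
        return pd.DataFrame(rows)


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF_j = 1/(1 - R^2) of column j regressed on the others (+ intercept)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot <= 0:
        return np.inf
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    r2 = min(r2, 1.0 - 1e-12)
    return float(1.0 / (1.0 - r2))


def vif_correlation_select(
    stack: EnvStack,
    sample_points: OccurrenceSet | tuple[np.ndarray, np.ndarray],
    r_threshold: float = 0.7,
    vif_threshold: float = 10.0,
) -> VarSelectionReport:
    """Two-stage collinearity screen over layer values at sample points.

    Stage 1 repeatedly finds the highest-|r| pair and drops the member with
    the larger mean |r| against all remaining variables, until every pairwise
    |r| <= ``r_threshold``.  Stage 2 drops the max-VIF variable until all
    VIF <= ``vif_threshold``.  Every drop is logged with its trigger value.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 candidate layers")
    if isinstance(sample_points, OccurrenceSet):
        x, y = sample_points.x, sample_points.y
    else:
        x, y = sample_points
    df = stack.values_at(x, y).dropna()
    if len(df) < 10 * len(stack.names):
        warnings.warn(
            f"only {len(df)} valid sample points for {len(stack.names)} "
            "candidates; selection may be unstable (>= 10x recommended)",
            stacklevel=2,
        )
    names = list(df.columns)
    full_r = df.corr()
    dropped: list[tuple[str, str]] = []

    def submatrix(cols):
        return df[cols].corr().to_numpy()

    # stage 1: pairwise correlation
    while len(names) > 1:
        R = np.abs(submatrix(names))
        np.fill_diagonal(R, 0.0)
        R = np.nan_to_num(R, nan=1.0)  # constant column vs anything: treat as collinear
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] <= r_threshold:
            break
        mean_i = R[i].sum() / (len(names) - 1)
        mean_j = R[j].sum() / (len(names) - 1)
        loser = i if mean_i >= mean_j else j
        dropped.append(
            (
                names[loser],
                f"|r|={R[i, j]:.3f} with "
                f"{names[j if loser == i else i]} (> {r_threshold})",
            )
        )
        del names[loser]

    # stage 2: variance inflation
    while len(names) > 1:
        X = df[names].to_numpy(float)
        vifs = np.array([_vif_one(X, j) for j in range(len(names))])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_threshold:
            break
        dropped.append((names[worst], f"VIF={vifs[worst]:.2f} (> {vif_threshold})"))
        del names[worst]

    X = df[names].to_numpy(float)
    vif = (
        {n: _vif_one(X, j) for j, n in enumerate(names)}
        if len(names) > 1
        else {names[0]: 1.0}
    )
    for n, why in dropped:
        log.info("variable %s dropped: %s", n, why)
    return VarSelectionReport(pairwise_r=full_r, vif=vif, kept=names, dropped=dropped)


# ----------------------------------------------------------------------
# Mantel correlogram


@dataclass
class MantelResult:
    """Distance-class-wise Mantel correlations with permutation p-values."""

    distance_classes: list[tuple[float, float]]
    r_per_class: np.ndarray
    p_per_class: np.ndarray
    n_pairs_per_class: np.ndarray
    n_permutations: int
    seed: int
    flagged: list[int] = field(default_factory=list)  # classes with < 2 pairs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower_m": [c[0] for c in self.distance_classes],
                "upper_m": [c[1] for c in self.distance_classes],
                "n_pairs": self.n_pairs_per_class,
                "mantel_r": self.r_per_class,
                "p_value": self.p_per_class,
            }
        )

    def warn_if_autocorrelated(self, r_cutoff: float = MANTEL_WARN_R) -> list[int]:
        """Diagnostic gate: warn (never thin) when any class shows r above
        the cutoff with p < 0.05."""
        hits = [
            k
            for k in range(len(self.distance_classes))
            if np.isfinite(self.r_per_class[k])
            and self.r_per_class[k] > r_cutoff
            and self.p_per_class[k] < 0.05
        ]
        if hits:
            warnings.warn(
                f"Mantel correlogram: {len(hits)} distance class(es) with "
                f"r > {r_cutoff} and p < 0.05; consider spatial thinning",
                stacklevel=2,
            )
        return hits


def mantel_correlogram(
    points: OccurrenceSet | tuple[np.ndarray, np.ndarray],
    env_values: np.ndarray,
    class_width: float = 50.0,
    max_distance: float = 1500.0,
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlogram of occurrences against their environment.

    For each geographic distance class the statistic is the (sign-flipped)
    Pearson correlation between the class-membership indicator of each point
    pair and the pairwise environmental distance, so positive r means nearby
    points are environmentally more similar than average (positive spatial
    autocorrelation).  One-sided p-values come from permuting point labels:
    ``p = (count(r_perm >= r_obs) + 1) / (n_permutations + 1)``.

    Classes with fewer than 2 pairs get NaN r and are listed in ``flagged``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if isinstance(points, OccurrenceSet):
        xy = np.column_stack([points.x, points.y])
    else:
        xy = np.column_stack(points)
    n = len(xy)
    if n < 10:
        raise ValueError(f"need >= 10 points, got {n}")
    env = np.asarray(env_values, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    if len(env) != n:
        raise ValueError("env_values must have one row per point")

    geo = pdist(xy)
    edges = np.arange(0.0, max_distance + class_width, class_width)
    classes = [(float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    # condensed env distance matrix, recomputable under row permutation
    envdist_sq = np.sqrt(((env[:, None, :] - env[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(n, k=1)
    envdist = envdist_sq[iu]

    n_total = len(geo)
    I = np.stack(
        [((geo >= lo) & (geo < hi)).astype(float) for lo, hi in classes]
    )  # (n_classes, n_pairs)
    n_pairs = I.sum(axis=1).astype(int)
    ind_mean = n_pairs / n_total
    ind_sd = np.sqrt(ind_mean * (1.0 - ind_mean))  # population sd of a 0/1 vector

    def all_class_r(ed: np.ndarray) -> np.ndarray:
        """Sign-flipped Pearson r of every class indicator against ``ed``."""
        e_sd = ed.std()
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = I @ ed / n_total - ind_mean * ed.mean()
            r = -cov / (ind_sd * e_sd)
        r[(n_pairs < 2) | (ind_sd == 0)] = np.nan
        if e_sd == 0:
            r[:] = np.nan
        return r

    r_obs = all_class_r(envdist)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(classes))
    valid = np.isfinite(r_obs)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ed = envdist_sq[np.ix_(perm, perm)][iu]
        rp = all_class_r(ed)
        exceed += valid & np.isfinite(rp) & (rp >= r_obs)
    p = np.where(valid, (exceed + 1.0) / (n_permutations + 1.0), np.nan)
    n_pairs = list(n_pairs)
    flagged = [k for k, np_k in enumerate(n_pairs) if np_k < 2]
    return MantelResult(
        distance_classes=classes,
        r_per_class=r_obs,
        p_per_class=p,
        n_pairs_per_class=np.array(n_pairs),
        n_permutations=n_permutations,
        seed=seed,
        flagged=flagged,
    )


# ----------------------------------------------------------------------
# record filtering


def filter_records(
    occ: OccurrenceSet, grid: Grid, land_mask: np.ndarray
) -> tuple[OccurrenceSet, dict[str, int]]:
    """Clean raw occurrences before modelling.

    Declared rule: drop exact duplicate coordinates, drop points off the land
    mask (or off-grid), then deduplicate to one record per cell per source.
    Returns the filtered set and a tally of removals by reason.
    """
    report = {"input": len(occ)}
    coords = np.column_stack([occ.x, occ.y])
    _, first = np.unique(coords, axis=0, return_index=True)
    keep = np.sort(first)
    report["exact_duplicates"] = len(occ) - len(keep)
    occ = occ.subset(keep)

    row, col = occ.cells_on(grid)
    on = (row >= 0) & (col >= 0)
    on[on] = land_mask[row[on], col[on]]
    report["off_land"] = int((~on).sum())
    occ = occ.subset(np.flatnonzero(on))

    row, col = occ.cells_on(grid)
    key = pd.DataFrame(
        {"cell": row * grid.n_cols + col, "source": occ.source.astype(str)}
    )
    keep = (~key.duplicated()).to_numpy()
    report["cell_source_duplicates"] = int((~keep).sum())
    occ = occ.subset(np.flatnonzero(keep))
    report["kept"] = len(occ)
    return occ, report
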