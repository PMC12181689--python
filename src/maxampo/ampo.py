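"""Areas of Maximum Probability of Occupancy (AMPO) and scenario change.

Each selected model's cloglog surface is thresholded at that model's own
kappa-maximising t*; the per-model binary maps are OR-combined into the
global AMPO.  Areas are planar (positive cells x cell area).  Overlap
statistics relate observed records to the AMPO and to probability cutoffs on
the ensemble mean surface.  Future projections re-apply each selected model
— with its frozen normalisers, clamp bounds and t* — to every SSP x GCM
climate stack while land cover and topography stay constant, and the change
in AMPO area is summarised per SSP and per GCM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .grid import EnvStack, Grid
from .maxent_core import MaxEntModel, predict_surface

__all__ = [
    "AMPOResult",
    "ScenarioOutcome",
    "binarize",
    "union_ampo",
    "area_km2",
    "polygonize",
    "occupancy_overlap",
    "project_scenarios",
    "area_change_stats",
]

# rook (4-neighbour) connectivity for polygon tracing
_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def binarize(surface: np.ndarray, threshold: float) -> np.ndarray:
    """Presence(1)/absence(0) map at a probability threshold; nodata kept.

    Cells with probability >= threshold are presence, matching the
    kappa-threshold rule used to score the models.
    """
    surface = np.asarray(surface, dtype=float)
    out = np.where(surface >= threshold, 1.0, 0.0)
    out[~np.isfinite(surface)] = np.nan
    return out


def area_km2(binary: np.ndarray, cell_size: float) -> float:
    """Planar area of positive cells: count x cell_size^2 / 1e6."""
    return float(np.nansum(np.asarray(binary) == 1) * cell_size**2 / 1e6)


def polygonize(binary: np.ndarray, grid: Grid) -> list:
    """Boundary polygons of positive regions, one per rook-connected
    component, with vertices at cell corners."""
    positive = np.nan_to_num(np.asarray(binary, dtype=float), nan=0.0) == 1
    labels, n_comp = ndimage.label(positive, structure=_ROOK)
    polys = []
    s = grid.cell_size
    x0, y0 = grid.origin
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == comp)
        cells = [
            box(x0 + c * s, y0 - (r + 1) * s, x0 + (c + 1) * s, y0 - r * s)
            for r, c in zip(rows, cols)
        ]
        polys.append(unary_union(cells))
    return polys


@dataclass
class AMPOResult:
    per_model_binary: list[np.ndarray]
    union_binary: np.ndarray
    polygons: list
    area_km2: float
    per_model_area_km2: list[float]


def union_ampo(binaries: list[np.ndarray], grid: Grid) -> AMPOResult:
    """Cellwise OR of per-model binary maps plus polygons and planar areas."""
    if not binaries:
        raise ValueError("need at least one binary raster")
    shapes = {np.asarray(b).shape for b in binaries}
    if len(shapes) > 1 or shapes.pop() != grid.shape:
        raise ValueError("all binary rasters must share the grid shape")
    stackd = np.stack([np.asarray(b, dtype=float) for b in binaries])
    any_pos = np.any(np.nan_to_num(stackd, nan=0.0) == 1, axis=0)
    union = np.where(any_pos, 1.0, 0.0)
    union[np.all(~np.isfinite(stackd), axis=0)] = np.nan
    return AMPOResult(
        per_model_binary=list(binaries),
        union_binary=union,
        polygons=polygonize(union, grid),
        area_km2=area_km2(union, grid.cell_size),
        per_model_area_km2=[area_km2(b, grid.cell_size) for b in binaries],
    )


# ----------------------------------------------------------------------
# occupancy overlap


def occupancy_overlap(
    records,
    mean_surface: np.ndarray,
    ampo_union: np.ndarray,
    grid: Grid,
    prob_cutoffs: tuple[float, ...] = (0.65, 0.5),
) -> dict:
    """How well observed records agree with the modelled occupancy.

    Returns the percentage of on-land records falling inside the union AMPO
    and, per cutoff, the percentage with a mean-surface probability *strictly
    greater* than the cutoff.  Records off the grid or on nodata cells are
    excluded from the denominators and tallied under ``off_grid``.
    """
    row, col = grid.point_to_cell(records.x, records.y)
    on = (row >= 0) & (col >= 0)
    if on.any():
        on_land = np.zeros_like(on)
        on_land[on] = np.isfinite(mean_surface[row[on], col[on]])
    else:
        on_land = on
    n_off = int((~on_land).sum())
    row, col = row[on_land], col[on_land]
    n = len(row)
    out = {"n_records": n, "off_grid": n_off}
    if n == 0:
        out["pct_in_ampo"] = np.nan
        for c in prob_cutoffs:
            out[f"pct_above_{c:g}"] = np.nan
        return out
    out["pct_in_ampo"] = float(100.0 * np.mean(ampo_union[row, col] == 1))
    probs = mean_surface[row, col]
    for c in prob_cutoffs:
        out[f"pct_above_{c:g}"] = float(100.0 * np.mean(probs > c))
    return out


# ----------------------------------------------------------------------
# future scenarios


@dataclass
class ScenarioOutcome:
    ssp: str
    gcm: str
    ampo: AMPOResult
    pct_change_vs_present: float


def project_scenarios(
    selected_models: list[tuple[MaxEntModel, float]],
    scenario_stacks: dict[tuple[str, str], EnvStack],
    constant_layers: EnvStack | None,
    present_area_km2: float,
) -> list[ScenarioOutcome]:
    """Project each selected model into every SSP x GCM scenario.

    ``selected_models`` pairs each model with its frozen kappa threshold t*.
    Scenario stacks carry the future climate; ``constant_layers`` (land cover
    and terrain) are merged in unchanged.  Per scenario the per-model binary
    maps are unioned and the AMPO area change vs the present is computed as
    (future - present) / present x 100.
    """
    if present_area_km2 <= 0:
        raise ValueError("present AMPO area must be positive")
    outcomes = []
    for (ssp, gcm), clim in sorted(scenario_stacks.items()):
        stack = clim if constant_layers is None else clim.merged(constant_layers)
        binaries = []
        for model, t_star in selected_models:
            missing = [v for v in model.variables if v not in stack]
            if missing:
                raise KeyError(
                    f"scenario ({ssp}, {gcm}) is missing model variable(s) {missing}"
                )
            surf = predict_surface(model, stack)
            binaries.append(binarize(surf.cloglog, t_star))
        result = union_ampo(binaries, stack.grid)
        pct = 100.0 * (result.area_km2 - present_area_km2) / present_area_km2
        outcomes.append(
            ScenarioOutcome(ssp=ssp, gcm=gcm, ampo=result, pct_change_vs_present=pct)
        )
    return outcomes


def area_change_stats(
    outcomes: list[ScenarioOutcome], present_area_km2: float
) -> pd.DataFrame:
    """Mean +- sample sd of AMPO change per SSP, per-GCM means, grand row."""
    if present_area_km2 <= 0:
        raise ValueError("present AMPO area must be positive")
    if not outcomes:
        raise ValueError("no scenario outcomes to summarise")
    df = pd.DataFrame(
        {
            "ssp": [o.ssp for o in outcomes],
            "gcm": [o.gcm for o in outcomes],
            "area_km2": [o.ampo.area_km2 for o in outcomes],
            "pct_change": [o.pct_change_vs_present for o in outcomes],
        }
    )
    rows = []
    for ssp, sub in df.groupby("ssp"):
        rows.append(
            {
                "group": "ssp",
                "label": ssp,
                "mean_pct_change": sub["pct_change"].mean(),
                "sd_pct_change": sub["pct_change"].std(ddof=1),
                "n": len(sub),
            }
        )
    for gcm, sub in df.groupby("gcm"):
        rows.append(
            {
                "group": "gcm",
                "label": gcm,
                "mean_pct_change": sub["pct_change"].mean(),
                "sd_pct_change": sub["pct_change"].std(ddof=1),
                "n": len(sub),
            }
        )
    rows.append(
        {
            "group": "all",
            "label": "all",
            "mean_pct_change": df["pct_change"].mean(),
            "sd_pct_change": df["pct_change"].std(ddof=1),
            "n": len(df),
        }
    )
    return pd.DataFrame(rows)
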