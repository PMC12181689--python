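"""End-to-end orchestration: one master seed, one declarative config.

Stage order mirrors how the analysis is run for real: simulate (or load)
inputs -> prepare predictors (terrain derivatives, land-cover fractions,
resampling) -> occurrence filtering and spatial-autocorrelation diagnostic ->
collinearity screen -> presence/background splits -> MaxEnt ensemble ->
AMPO and record overlap -> SSP x GCM future projection -> report.

Every random draw (island, splits, background, per-run clamps) is derived
from ``master_seed`` through fixed-purpose seed channels, so a rerun with the
same config and seed is bit-identical end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import __version__
from .ampo import (
    AMPOResult,
    ScenarioOutcome,
    area_change_stats,
    binarize,
    occupancy_overlap,
    project_scenarios,
    union_ampo,
)
from .env_layers import (
    MantelResult,
    VarSelectionReport,
    bilinear_resample,
    filter_records,
    landcover_to_pft,
    mantel_correlogram,
    terrain_derivatives,
    vif_correlation_select,
)
from .grid import EnvStack, OccurrenceSet, write_ascii_grid
from .model_ensemble import EnsembleResult, SplitSpec, run_ensemble, sample_background, split_presences
from .synthetic_island import (
    DEFAULT_CROSSWALK,
    GCM_LABELS,
    SSP_LABELS,
    SyntheticIsland,
    SyntheticIslandConfig,
    default_shift_table,
    perturb_future,
    simulate_island,
    standardise_layers,
)

log = logging.getLogger("maxampo")

# fixed seed channels (master_seed, channel) -> independent streams
_SEED_CHANNELS = {"island": 0, "split": 1, "background": 2, "ensemble": 3, "mantel": 4}


def derive_seed(master_seed: int, channel: str) -> int:
    """Deterministic sub-seed for one named purpose (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), _SEED_CHANNELS[channel]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    ``predictors`` defaults to the nine-variable set: the four climate
    layers, three cover fractions (tree, grass, crop) and two terrain
    variables (slope, aspect).  Elevation and roughness are computed but
    excluded from the default model.
    """

    island: SyntheticIslandConfig = field(default_factory=SyntheticIslandConfig)
    predictors: list[str] | None = None
    train_fraction: float = 0.8
    n_background: int = 2000
    n_models: int = 100
    k_best: int = 10
    beta_multiplier: float = 1.0
    n_background_subsample: int = 8000
    clamp_quantile_window: tuple = ((0.0, 0.05), (0.95, 1.0))
    t_grid_step: float = 0.01
    prob_cutoffs: tuple = (0.65, 0.5)
    r_threshold: float = 0.7
    vif_threshold: float = 10.0
    mantel_class_width: float = 200.0
    mantel_max_distance: float = 2000.0
    mantel_n_permutations: int = 199
    mantel_max_points: int = 150
    scenario_noise_sd: float = 0.0
    ssps: tuple = SSP_LABELS
    gcms: tuple = GCM_LABELS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_models >= self.k_best >= 1:
            raise ValueError("need n_models >= k_best >= 1")
        if not 0 < self.t_grid_step < 1:
            raise ValueError("t_grid_step must be in (0, 1)")

    def default_predictors(self) -> list[str]:
        return self.island.climate_names() + ["tree", "grass", "crop", "slope", "aspect"]

    def t_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.t_grid_step, 1.0, self.t_grid_step),
            int(np.ceil(-np.log10(self.t_grid_step))),
        )

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["island"] = dataclasses.asdict(self.island)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "island" in data and isinstance(data["island"], dict):
            ik = {f.name for f in dataclasses.fields(SyntheticIslandConfig)}
            bad = set(data["island"]) - ik
            if bad:
                raise ValueError(f"unknown island config keys: {sorted(bad)}")
            isl = dict(data["island"])
            if "true_coefficients" in isl:
                isl["true_coefficients"] = tuple(isl["true_coefficients"])
            data["island"] = SyntheticIslandConfig(**isl)
        for key in ("prob_cutoffs", "ssps", "gcms"):
            if key in data:
                data[key] = tuple(data[key])
        if "clamp_quantile_window" in data:
            lo, hi = data["clamp_quantile_window"]
            data["clamp_quantile_window"] = (tuple(lo), tuple(hi))
        if "predictors" in data and data["predictors"] is not None:
            data["predictors"] = list(data["predictors"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    island: SyntheticIsland
    predictor_stack: EnvStack
    constant_stack: EnvStack
    records: OccurrenceSet
    filter_report: dict
    mantel: MantelResult
    selection: VarSelectionReport
    ensemble: EnsembleResult
    present_ampo: AMPOResult
    overlap: dict
    scenario_outcomes: list[ScenarioOutcome]
    change_stats: pd.DataFrame
    truth_spearman: float
    seeds: dict


def prepare_predictors(island: SyntheticIsland) -> tuple[EnvStack, EnvStack]:
    """Build the full predictor stack on the DEM grid.

    Returns (full stack incl. climate, cover fractions, terrain) and the
    non-climate constant stack reused unchanged across future scenarios.
    """
    terrain = terrain_derivatives(island.dem, island.grid)
    pft_coarse = landcover_to_pft(
        island.landcover, island.landcover_grid, DEFAULT_CROSSWALK
    )
    pft = EnvStack(
        island.grid,
        {
            name: bilinear_resample(pft_coarse[name], island.landcover_grid, island.grid)
            for name in pft_coarse.names
        },
    )
    constant = EnvStack(island.grid, {})
    for name in pft.names:
        constant[name] = pft[name]
    for name in ("elevation", "slope", "aspect", "roughness"):
        constant[name] = terrain[name]
    return island.climate.merged(constant), constant


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and return the in-memory results bundle."""
    seeds = {ch: derive_seed(config.master_seed, ch) for ch in _SEED_CHANNELS}
    log.info("run configuration:\n%s", config.to_yaml())

    island_cfg = dataclasses.replace(config.island, seed=seeds["island"])
    island = simulate_island(island_cfg)

    full_stack, constant = prepare_predictors(island)
    predictors = config.predictors or config.default_predictors()
    stack = full_stack.subset(predictors)
    land = stack.land_mask()

    records, filter_report = filter_records(
        island.truth.presence_points, island.grid, land
    )

    # spatial-autocorrelation diagnostic on a capped subsample of records
    rng = np.random.default_rng(seeds["mantel"])
    idx = np.arange(len(records))
    if len(idx) > config.mantel_max_points:
        idx = np.sort(rng.choice(idx, size=config.mantel_max_points, replace=False))
    pts = records.subset(idx)
    env_std = standardise_layers(stack)
    env_at = env_std.values_at(pts.x, pts.y).to_numpy(float)
    ok = np.all(np.isfinite(env_at), axis=1)
    mantel = mantel_correlogram(
        (pts.x[ok], pts.y[ok]),
        env_at[ok],
        class_width=config.mantel_class_width,
        max_distance=config.mantel_max_distance,
        n_permutations=config.mantel_n_permutations,
        seed=seeds["mantel"],
    )
    mantel.warn_if_autocorrelated()

    selection = vif_correlation_select(
        stack,
        (records.x, records.y),
        r_threshold=config.r_threshold,
        vif_threshold=config.vif_threshold,
    )

    p_train, p_test = split_presences(
        records, SplitSpec(train_fraction=config.train_fraction, seed=seeds["split"])
    )
    b_train, b_test = sample_background(
        island.grid,
        config.n_background,
        seed=seeds["background"],
        mask=land,
        train_fraction=config.train_fraction,
    )

    ensemble = run_ensemble(
        p_train,
        p_test,
        b_train,
        b_test,
        stack,
        n_models=config.n_models,
        k_best=config.k_best,
        master_seed=seeds["ensemble"],
        n_background_subsample=config.n_background_subsample,
        beta_multiplier=config.beta_multiplier,
        quantile_window=config.clamp_quantile_window,
        t_grid=config.t_grid(),
    )

    binaries = [
        binarize(surf.cloglog, rec.metrics.threshold_at_kappa_max)
        for surf, rec in zip(ensemble.selected_surfaces, ensemble.selected_runs)
    ]
    present_ampo = union_ampo(binaries, island.grid)
    overlap = occupancy_overlap(
        records,
        ensemble.mean_surface.cloglog,
        present_ampo.union_binary,
        island.grid,
        prob_cutoffs=config.prob_cutoffs,
    )

    shift_table = default_shift_table(island_cfg.climate_names())
    scenario_stacks = {}
    for ssp in config.ssps:
        for gcm in config.gcms:
            scenario_stacks[(ssp, gcm)] = perturb_future(
                island.climate,
                ssp,
                gcm,
                shift_table,
                seed=seeds["ensemble"],
                noise_sd=config.scenario_noise_sd,
            )
    selected_models = [
        (rec.model, rec.metrics.threshold_at_kappa_max)
        for rec in ensemble.selected_runs
    ]
    # only climate layers the models actually use need to travel per scenario
    outcomes = project_scenarios(
        selected_models, scenario_stacks, constant, present_ampo.area_km2
    )
    stats = area_change_stats(outcomes, present_ampo.area_km2)

    both = np.isfinite(ensemble.mean_surface.cloglog) & np.isfinite(
        island.truth.suitability
    )
    rho = float(
        spearmanr(
            ensemble.mean_surface.cloglog[both], island.truth.suitability[both]
        ).statistic
    )

    return PipelineResult(
        config=config,
        island=island,
        predictor_stack=stack,
        constant_stack=constant,
        records=records,
        filter_report=filter_report,
        mantel=mantel,
        selection=selection,
        ensemble=ensemble,
        present_ampo=present_ampo,
        overlap=overlap,
        scenario_outcomes=outcomes,
        change_stats=stats,
        truth_spearman=rho,
        seeds=seeds,
    )


# ----------------------------------------------------------------------
# disk outputs


def write_simulation(island: SyntheticIsland, out_dir) -> list[Path]:
    """Write the synthetic dataset: rasters, occurrences CSV, truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    write_ascii_grid(out / "dem.asc", island.dem, island.grid)
    written.append(out / "dem.asc")
    written += island.climate.write_dir(out)
    write_ascii_grid(out / "landcover.asc", island.landcover, island.landcover_grid)
    written.append(out / "landcover.asc")
    island.truth.presence_points.to_csv(out / "occurrences.csv")
    written.append(out / "occurrences.csv")
    island.truth.write_sidecar(out / "truth.txt")
    written.append(out / "truth.txt")
    write_ascii_grid(out / "true_suitability.asc", island.truth.suitability, island.grid)
    written.append(out / "true_suitability.asc")
    return written


def _result_digest(result: PipelineResult) -> str:
    h = hashlib.sha256()
    h.update(result.config.to_yaml().encode())
    h.update(np.round(result.ensemble.mean_surface.cloglog, 9).tobytes())
    h.update(result.ensemble.metrics_table().to_csv(index=False).encode())
    h.update(result.change_stats.to_csv(index=False).encode())
    h.update(json.dumps(result.overlap, sort_keys=True).encode())
    return h.hexdigest()


def summary_dict(result: PipelineResult) -> dict:
    """Headline numbers of a run, JSON-serialisable."""
    sel = result.ensemble.selected_runs
    per_ssp = {
        row["label"]: row["mean_pct_change"]
        for _, row in result.change_stats.iterrows()
        if row["group"] == "ssp"
    }
    per_gcm = {
        row["label"]: row["mean_pct_change"]
        for _, row in result.change_stats.iterrows()
        if row["group"] == "gcm"
    }
    return {
        "n_records": len(result.records),
        "n_presence_train": len(
            split_presences(
                result.records,
                SplitSpec(result.config.train_fraction, result.seeds["split"]),
            )[0]
        ),
        "mean_selected_auc": float(np.mean([r.metrics.auc for r in sel])),
        "min_selected_auc": float(np.min([r.metrics.auc for r in sel])),
        "present_ampo_km2": result.present_ampo.area_km2,
        "truth_spearman": result.truth_spearman,
        "n_scenarios": len(result.scenario_outcomes),
        "overlap": result.overlap,
        "mean_pct_change_per_ssp": per_ssp,
        "mean_pct_change_per_gcm": per_gcm,
    }


def write_results(result: PipelineResult, out_dir) -> Path:
    """Write rasters, tables, report.md and the machine-readable manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = result.island.grid

    write_ascii_grid(out / "mean_suitability.asc", result.ensemble.mean_surface.cloglog, grid)
    write_ascii_grid(out / "ampo_union.asc", result.present_ampo.union_binary, grid)
    result.ensemble.metrics_table().to_csv(out / "run_metrics.csv", index=False)
    result.selection.to_dataframe().to_csv(out / "variable_selection.csv", index=False)
    result.mantel.to_dataframe().to_csv(out / "mantel_correlogram.csv", index=False)
    result.change_stats.to_csv(out / "area_change_stats.csv", index=False)
    scen = pd.DataFrame(
        {
            "ssp": [o.ssp for o in result.scenario_outcomes],
            "gcm": [o.gcm for o in result.scenario_outcomes],
            "ampo_km2": [o.ampo.area_km2 for o in result.scenario_outcomes],
            "pct_change": [o.pct_change_vs_present for o in result.scenario_outcomes],
        }
    )
    scen.to_csv(out / "scenario_outcomes.csv", index=False)
    # polygon boundaries as WKT, one row per rook-connected component
    with (out / "ampo_polygons.wkt").open("w") as fh:
        for poly in result.present_ampo.polygons:
            fh.write(poly.wkt + "\n")

    manifest = {
        "package_version": __version__,
        "master_seed": result.config.master_seed,
        "derived_seeds": result.seeds,
        "config": result.config.to_dict(),
        "result_digest": _result_digest(result),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(
        json.dumps(summary_dict(result), indent=2, default=str)
    )
    (out / "report.md").write_text(_render_report(result, scen))
    return out


def _render_report(result: PipelineResult, scen: pd.DataFrame) -> str:
    sel = result.ensemble.selected_runs
    ov = result.overlap
    lines = [
        "# Ensemble habitat-suitability run report",
        "",
        "## Model performance (selected runs)",
        "",
        result.ensemble.metrics_table()
        .query("selected")
        .to_string(index=False),
        "",
        f"Mean selected test AUC: {np.mean([r.metrics.auc for r in sel]):.3f}",
        "",
        "## Occupancy area",
        "",
        f"Present AMPO (union of {len(sel)} model areas): "
        f"{result.present_ampo.area_km2:.2f} km^2 over "
        f"{len(result.present_ampo.polygons)} polygon(s).",
        f"Per-model areas (km^2): "
        + ", ".join(f"{a:.2f}" for a in result.present_ampo.per_model_area_km2),
        "",
        "## Record overlap",
        "",
        f"{ov['n_records']} records on land ({ov['off_grid']} off-grid/off-land).",
        f"Inside AMPO: {ov['pct_in_ampo']:.1f}%",
    ]
    for c in result.config.prob_cutoffs:
        lines.append(f"Above {c:g} probability: {ov[f'pct_above_{c:g}']:.1f}%")
    lines += [
        "",
        "## Future scenarios",
        "",
        scen.to_string(index=False),
        "",
        result.change_stats.to_string(index=False),
        "",
        "## Ground-truth recovery",
        "",
        f"Spearman rho between ensemble mean surface and true suitability: "
        f"{result.truth_spearman:.3f}",
    ]
    return "\n".join(lines) + "\n"
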