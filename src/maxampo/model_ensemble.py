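"""Ensemble of randomly-clamped MaxEnt runs with AUC-based selection.

Procedure: split presences 80/20 (floor rule), sample background points
uniformly over land and split them the same way, then fit ``n_models``
MaxEnt runs that differ by a seeded random clamp specification and a seeded
subsample of the training background.  Each run is scored on the held-out
presences and background (AUC, Cohen's-kappa curve and the derived
threshold metrics); the ``k_best`` runs with the highest test AUC are kept
and their cloglog surfaces averaged cellwise into the ensemble mean surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid import EnvStack, Grid, OccurrenceSet
from .maxent_core import (
    MaxEntModel,
    SuitabilitySurface,
    predict_raw,
    predict_surface,
    random_clamp_spec,
    to_cloglog,
    train_maxent,
)

__all__ = [
    "SplitSpec",
    "EvalMetrics",
    "EnsembleResult",
    "split_presences",
    "sample_background",
    "auc",
    "confusion_metrics",
    "kappa_max_threshold",
    "evaluate_scores",
    "run_ensemble",
    "DEFAULT_T_GRID",
]

log = logging.getLogger("maxampo")

DEFAULT_T_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition rule: train size = floor(train_fraction * N)."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    def sizes(self, n: int) -> tuple[int, int]:
        n_train = int(np.floor(self.train_fraction * n))
        return n_train, n - n_train


def split_presences(
    occurrences: OccurrenceSet, spec: SplitSpec
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded uniform random partition into disjoint, exhaustive train/test."""
    n = len(occurrences)
    if n < 10:
        raise ValueError(f"need >= 10 presences to split, got {n}")
    n_train, n_test = spec.sizes(n)
    if n_test == 0:
        raise ValueError("split would leave an empty test set")
    perm = np.random.default_rng(spec.seed).permutation(n)
    return occurrences.subset(np.sort(perm[:n_train])), occurrences.subset(
        np.sort(perm[n_train:])
    )


def sample_background(
    grid: Grid,
    n: int,
    seed: int,
    mask: np.ndarray | None = None,
    train_fraction: float = 0.8,
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Uniform background sample over land cells, pre-split train/test.

    Draws ``n`` distinct cell centres without replacement (uniformly over the
    mask, or the whole grid if no mask) and splits them by the same floor
    rule as the presences.
    """
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    cells = np.flatnonzero(mask.ravel())
    if n > cells.size:
        raise ValueError(f"requested {n} background points but only {cells.size} cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, grid.shape)
    x, y = grid.cell_centre(rows, cols)
    occ = OccurrenceSet.from_arrays(x, y, source="background", date="")
    return split_presences(occ, SplitSpec(train_fraction=train_fraction, seed=seed))


# ----------------------------------------------------------------------
# evaluation metrics


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def confusion_metrics(
    presence_scores, background_scores, threshold: float
) -> tuple[float, float, float, float]:
    """(type1, type2, ppp, kappa) at ``score >= threshold`` = predicted presence.

    type1 = FP/(FP+TN) on background, type2 = FN/(FN+TP) on presences,
    ppp = (TP+FP)/all; kappa = (p_o - p_e)/(1 - p_e) with chance agreement
    from the marginal products, defined as 0 when p_e = 1.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    tp = float((p >= threshold).sum())
    fn = float(p.size) - tp
    fp = float((b >= threshold).sum())
    tn = float(b.size) - fp
    total = tp + fn + fp + tn
    type1 = fp / (fp + tn) if (fp + tn) else 0.0
    type2 = fn / (fn + tp) if (fn + tp) else 0.0
    ppp = (tp + fp) / total
    p_o = (tp + tn) / total
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / total**2
    kappa = 0.0 if np.isclose(p_e, 1.0) else (p_o - p_e) / (1.0 - p_e)
    return type1, type2, ppp, float(kappa)


def kappa_max_threshold(
    presence_scores, background_scores, t_grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Exhaustive scan for the kappa-maximising threshold t*.

    Ties break toward the lowest threshold (first grid point attaining the
    maximum).
    """
    if t_grid is None:
        t_grid = DEFAULT_T_GRID
    kappas = np.array(
        [confusion_metrics(presence_scores, background_scores, t)[3] for t in t_grid]
    )
    best = int(np.argmax(kappas))  # argmax returns the first maximiser
    return float(t_grid[best]), float(kappas[best])


@dataclass
class EvalMetrics:
    """Per-model test-set evaluation bundle."""

    auc: float
    kappa_curve: pd.Series  # threshold -> kappa
    kappa_max: float
    threshold_at_kappa_max: float
    type1: float
    type2: float
    ppp: float


def evaluate_scores(
    presence_scores, background_scores, t_grid: np.ndarray | None = None
) -> EvalMetrics:
    """AUC plus the full kappa-vs-threshold curve and metrics at t*."""
    if t_grid is None:
        t_grid = DEFAULT_T_GRID
    kappas = np.array(
        [confusion_metrics(presence_scores, background_scores, t)[3] for t in t_grid]
    )
    best = int(np.argmax(kappas))
    t_star = float(t_grid[best])
    type1, type2, ppp, kappa = confusion_metrics(
        presence_scores, background_scores, t_star
    )
    return EvalMetrics(
        auc=auc(presence_scores, background_scores),
        kappa_curve=pd.Series(kappas, index=np.asarray(t_grid)),
        kappa_max=float(kappa),
        threshold_at_kappa_max=t_star,
        type1=type1,
        type2=type2,
        ppp=ppp,
    )


# ----------------------------------------------------------------------
# the 100-run ensemble


@dataclass
class RunRecord:
    run_id: int
    seed: int
    model: MaxEntModel
    metrics: EvalMetrics


@dataclass
class EnsembleResult:
    runs: list[RunRecord]
    selected: list[int]  # indices into runs, best test AUC first
    mean_surface: SuitabilitySurface
    selected_surfaces: list[SuitabilitySurface]
    warnings: list[str] = field(default_factory=list)

    @property
    def selected_runs(self) -> list[RunRecord]:
        return [self.runs[i] for i in self.selected]

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.runs:
            m = rec.metrics
            rows.append(
                {
                    "run_id": rec.run_id,
                    "seed": rec.seed,
                    "auc": m.auc,
                    "kappa_max": m.kappa_max,
                    "t_star": m.threshold_at_kappa_max,
                    "type1": m.type1,
                    "type2": m.type2,
                    "ppp": m.ppp,
                    "converged": rec.model.converged,
                    "selected": rec.run_id in self.selected,
                }
            )
        return pd.DataFrame(rows)


def run_ensemble(
    presence_train: OccurrenceSet,
    presence_test: OccurrenceSet,
    background_train: OccurrenceSet,
    background_test: OccurrenceSet,
    stack: EnvStack,
    n_models: int = 100,
    k_best: int = 10,
    master_seed: int = 0,
    n_background_subsample: int = 8000,
    beta_multiplier: float = 1.0,
    classes: list[str] | str = "auto",
    n_hinge_knots: int = 8,
    quantile_window=((0.0, 0.05), (0.95, 1.0)),
    t_grid: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> EnsembleResult:
    """Fit, evaluate and select the MaxEnt ensemble.

    Every run derives its own seed from ``master_seed``, draws a random clamp
    spec from the training-background distribution and a background subsample
    of ``n_background_subsample`` training points, fits, and is evaluated on
    the test presences vs test background.  The ``k_best`` runs by test AUC
    (ties to the lower run index) are selected; their cloglog surfaces over
    the stack are averaged into the mean surface.
    """
    if not n_models >= k_best >= 1:
        raise ValueError("need n_models >= k_best >= 1")
    env_p_train = stack.values_at(presence_train.x, presence_train.y).dropna()
    env_p_test = stack.values_at(presence_test.x, presence_test.y).dropna()
    env_b_train = stack.values_at(background_train.x, background_train.y).dropna()
    env_b_test = stack.values_at(background_test.x, background_test.y).dropna()

    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master_seed).spawn(n_models)
    ]
    notes: list[str] = []
    runs: list[RunRecord] = []
    for i, run_seed in enumerate(seeds):
        rng = np.random.default_rng(run_seed)
        clamp = random_clamp_spec(
            env_b_train, quantile_window=quantile_window, seed=run_seed
        )
        n_sub = min(n_background_subsample, len(env_b_train))
        sub = rng.choice(len(env_b_train), size=n_sub, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-background warning handled here
            model = train_maxent(
                env_p_train,
                env_b_train.iloc[np.sort(sub)],
                classes=classes,
                n_hinge_knots=n_hinge_knots,
                clamp=clamp,
                beta_multiplier=beta_multiplier,
                max_iter=max_iter,
                tol=tol,
                seed=run_seed,
            )
        p_scores = to_cloglog(predict_raw(model, env_p_test), model.entropy)
        b_scores = to_cloglog(predict_raw(model, env_b_test), model.entropy)
        metrics = evaluate_scores(p_scores, b_scores, t_grid)
        runs.append(RunRecord(run_id=i, seed=run_seed, model=model, metrics=metrics))

    aucs = np.array([r.metrics.auc for r in runs])
    # stable sort on -auc: ties resolve to the lower run index
    order = np.argsort(-aucs, kind="stable")
    selected = [int(j) for j in order[:k_best]]
    for j in selected:
        if not runs[j].model.converged:
            notes.append(f"selected run {j} did not converge")
            log.warning("selected run %d did not converge", j)

    surfaces = [predict_surface(runs[j].model, stack) for j in selected]
    mean_clog = np.mean([s.cloglog for s in surfaces], axis=0)
    mean_raw = np.mean([s.raw for s in surfaces], axis=0)
    mean_surface = SuitabilitySurface(grid=stack.grid, raw=mean_raw, cloglog=mean_clog)
    return EnsembleResult(
        runs=runs,
        selected=selected,
        mean_surface=mean_surface,
        selected_surfaces=surfaces,
        warnings=notes,
    )
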