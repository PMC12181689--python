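"""Presence-only maximum-entropy model, written from scratch.

The model estimates a Gibbs distribution q_lambda(x) = exp(lambda . f(x)) / Z
over background locations whose feature expectations match the presence
sample, subject to an L1 penalty:

    maximise  (1/m) sum_i lambda . f(x_i)  -  log Z_lambda
              -  sum_j beta_j |lambda_j|

with Z_lambda = sum_background exp(lambda . f(x)).  The problem is concave;
the optimiser is monotone proximal-gradient descent with backtracking and
soft-thresholding for the L1 term.  Features follow the conventional MaxEnt
classes (linear, quadratic, product, hinge, threshold), all scaled into
[0, 1] using training-background normalisers.  The map-scale output is the
complementary log-log transform p = 1 - exp(-e^H * q) where H is the entropy
of the fitted distribution over the training background.

Random clamping — drawing per-variable projection bounds from seeded quantile
windows of the training distribution — is the per-run diversity mechanism for
the ensemble and is isolated in :func:`random_clamp_spec` so the policy can
be swapped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grid import EnvStack, Grid

__all__ = [
    "FeatureSpec",
    "FeatureExpander",
    "ClampSpec",
    "MaxEntModel",
    "SuitabilitySurface",
    "build_features",
    "auto_feature_classes",
    "fit_maxent",
    "train_maxent",
    "predict_raw",
    "predict_surface",
    "to_cloglog",
    "random_clamp_spec",
    "apply_clamp",
    "save_model",
    "load_model",
]

log = logging.getLogger("maxampo")

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

# Default per-class regularisation multipliers (mainstream MaxEnt practice:
# hinge features are penalised more lightly, thresholds more heavily).
DEFAULT_CLASS_MULTIPLIERS = {
    "linear": 1.0,
    "quadratic": 1.0,
    "product": 1.0,
    "hinge": 0.5,
    "threshold": 1.0,
}


@dataclass(frozen=True)
class FeatureSpec:
    kind: str
    variables: tuple[str, ...]
    knot: float | None = None
    direction: str | None = None  # hinge only: "forward" or "reverse"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "product" and len(self.variables) != 2:
            raise ValueError("product features need exactly 2 variables")
        if self.kind in ("hinge", "threshold") and self.knot is None:
            raise ValueError(f"{self.kind} feature needs a knot")
        if self.kind == "hinge" and self.direction not in ("forward", "reverse"):
            raise ValueError("hinge feature needs direction forward|reverse")

    @property
    def label(self) -> str:
        parts = [self.kind, "*".join(self.variables)]
        if self.knot is not None:
            parts.append(f"{self.knot:g}")
        if self.direction:
            parts.append(self.direction)
        return ":".join(parts)


def auto_feature_classes(n_presence: int) -> list[str]:
    """Feature classes by presence count: below 80 records the sparser
    linear+quadratic+hinge set, from 80 up all five classes."""
    if n_presence < 80:
        return ["linear", "quadratic", "hinge"]
    return list(FEATURE_CLASSES)


class FeatureExpander:
    """Turns a predictor table into the [0, 1]-scaled design matrix.

    Normalisers (per-variable min/max) and hinge/threshold knots come from
    the table the expander is fitted on — by convention the training
    background.  Constant predictors keep a (constant-zero) linear column but
    their nonlinear features are suppressed with a logged warning.
    """

    def __init__(self, classes: list[str], n_hinge_knots: int = 8) -> None:
        unknown = set(classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        self.classes = list(classes)
        self.n_hinge_knots = int(n_hinge_knots)
        self.variables: list[str] = []
        self.normalisers: dict[str, tuple[float, float]] = {}
        self.specs: list[FeatureSpec] = []

    # -- fitting --------------------------------------------------------
    def fit(self, table: pd.DataFrame) -> "FeatureExpander":
        if not np.all(np.isfinite(table.to_numpy(float))):
            raise ValueError("training table contains non-finite values")
        self.variables = list(table.columns)
        self.normalisers = {
            v: (float(table[v].min()), float(table[v].max())) for v in self.variables
        }
        constant = [v for v in self.variables if self.normalisers[v][0] == self.normalisers[v][1]]
        if constant:
            log.warning(
                "constant predictors %s: nonlinear features suppressed", constant
            )
        specs: list[FeatureSpec] = []
        varying = [v for v in self.variables if v not in constant]
        if "linear" in self.classes:
            specs += [FeatureSpec("linear", (v,)) for v in self.variables]
        if "quadratic" in self.classes:
            specs += [FeatureSpec("quadratic", (v,)) for v in varying]
        if "product" in self.classes:
            for i, v in enumerate(varying):
                for w in varying[i + 1 :]:
                    specs.append(FeatureSpec("product", (v, w)))
        qs = np.linspace(0, 1, self.n_hinge_knots + 2)[1:-1]
        for v in varying:
            knots = np.unique(np.quantile(table[v].to_numpy(float), qs))
            mn, mx = self.normalisers[v]
            if "hinge" in self.classes:
                for knot in knots:
                    if knot < mx:
                        specs.append(FeatureSpec("hinge", (v,), float(knot), "forward"))
                    if knot > mn:
                        specs.append(FeatureSpec("hinge", (v,), float(knot), "reverse"))
            if "threshold" in self.classes:
                for knot in knots:
                    if mn < knot < mx:
                        specs.append(FeatureSpec("threshold", (v,), float(knot)))
        self.specs = specs
        return self

    # -- application ----------------------------------------------------
    def _scaled(self, table: pd.DataFrame, v: str) -> np.ndarray:
        mn, mx = self.normalisers[v]
        x = table[v].to_numpy(float)
        if mx == mn:
            return np.zeros_like(x)
        return np.clip((x - mn) / (mx - mn), 0.0, 1.0)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in table.columns]
        if missing:
            raise KeyError(f"missing model variables: {missing}")
        if not self.specs:
            raise RuntimeError("expander not fitted")
        cols = []
        for spec in self.specs:
            v = spec.variables[0]
            if spec.kind == "linear":
                cols.append(self._scaled(table, v))
            elif spec.kind == "quadratic":
                cols.append(self._scaled(table, v) ** 2)
            elif spec.kind == "product":
                cols.append(self._scaled(table, v) * self._scaled(table, spec.variables[1]))
            elif spec.kind == "hinge":
                x = table[v].to_numpy(float)
                mn, mx = self.normalisers[v]
                if spec.direction == "forward":
                    span = mx - spec.knot
                    col = np.maximum(0.0, x - spec.knot) / span
                else:
                    span = spec.knot - mn
                    col = np.maximum(0.0, spec.knot - x) / span
                cols.append(np.clip(col, 0.0, 1.0))
            else:  # threshold
                x = table[v].to_numpy(float)
                cols.append((x > spec.knot).astype(float))
        X = np.column_stack(cols) if cols else np.empty((len(table), 0))
        if np.any(~np.isfinite(X)):
            raise ValueError("NaN/inf in feature matrix; clean inputs first")
        return X

    @property
    def kinds(self) -> np.ndarray:
        return np.array([s.kind for s in self.specs])


def build_features(
    values_table: pd.DataFrame,
    classes: list[str] | str = "auto",
    n_hinge_knots: int = 8,
) -> tuple[np.ndarray, FeatureExpander]:
    """Fit an expander on ``values_table`` and return its design matrix."""
    if classes == "auto":
        classes = auto_feature_classes(len(values_table))
    expander = FeatureExpander(classes, n_hinge_knots).fit(values_table)
    return expander.transform(values_table), expander


# ----------------------------------------------------------------------
# clamping


@dataclass
class ClampSpec:
    """Per-variable projection bounds drawn from training quantile windows."""

    bounds: dict[str, tuple[float, float]]
    quantiles: dict[str, tuple[float, float]]
    seed: int | None = None

    def __post_init__(self) -> None:
        for v, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"crossed clamp bounds for {v!r}: {lo} > {hi}")


def random_clamp_spec(
    training_values: pd.DataFrame,
    quantile_window: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 0.05),
        (0.95, 1.0),
    ),
    seed: int | None = None,
) -> ClampSpec:
    """Draw seeded random clamp bounds per variable.

    The lower bound is the training quantile at a level drawn uniformly from
    ``quantile_window[0]``, the upper from ``quantile_window[1]``; disjoint
    windows make crossed bounds impossible.  The degenerate window
    ``((0, 0), (1, 1))`` reproduces plain min/max clamping (identity on the
    training data).
    """
    (lo_a, lo_b), (hi_a, hi_b) = quantile_window
    if not (0 <= lo_a <= lo_b <= hi_a <= hi_b <= 1):
        raise ValueError("quantile windows must be ordered and within [0, 1]")
    rng = np.random.default_rng(seed)
    bounds, quants = {}, {}
    for v in training_values.columns:
        ql = float(rng.uniform(lo_a, lo_b))
        qh = float(rng.uniform(hi_a, hi_b))
        x = training_values[v].to_numpy(float)
        bounds[v] = (float(np.quantile(x, ql)), float(np.quantile(x, qh)))
        quants[v] = (ql, qh)
    return ClampSpec(bounds=bounds, quantiles=quants, seed=seed)


def apply_clamp(table: pd.DataFrame, clamp: ClampSpec | None) -> pd.DataFrame:
    if clamp is None:
        return table
    out = table.copy()
    for v, (lo, hi) in clamp.bounds.items():
        if v in out.columns:
            out[v] = out[v].clip(lo, hi)
    return out


# ----------------------------------------------------------------------
# model fit


@dataclass
class MaxEntModel:
    expander: FeatureExpander
    weights: np.ndarray
    reg_weights: np.ndarray
    clamp: ClampSpec | None
    log_partition: float
    entropy: float
    n_background: int
    converged: bool
    seed: int | None = None
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def features(self) -> list[FeatureSpec]:
        return self.expander.specs

    @property
    def variables(self) -> list[str]:
        return self.expander.variables


@dataclass
class SuitabilitySurface:
    """Raw (relative occurrence rate) and cloglog rasters on one grid."""

    grid: Grid
    raw: np.ndarray
    cloglog: np.ndarray


def _penalised_objective(lam, Xp_mean, Xb, betas):
    return float(Xp_mean @ lam - logsumexp(Xb @ lam) - betas @ np.abs(lam))


def fit_maxent(
    presence_matrix: np.ndarray,
    background_matrix: np.ndarray,
    beta_multiplier: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    feature_kinds: np.ndarray | None = None,
    betas: np.ndarray | None = None,
    class_multipliers: dict[str, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """L1-penalised MaxEnt fit on pre-built feature matrices.

    Unless ``betas`` overrides them, per-feature penalties are
    ``beta_j = beta_multiplier * c_kind * s_j / sqrt(m)`` with ``s_j`` the
    presence-sample standard deviation of feature j (floored at 1e-3 so
    degenerate features stay penalised) and ``c_kind`` the per-class
    multiplier.  Returns the weight vector and a diagnostics dict with the
    per-iteration penalised objective (non-decreasing by construction),
    log-partition, entropy and convergence flag.
    """
    Xp = np.asarray(presence_matrix, dtype=float)
    Xb = np.asarray(background_matrix, dtype=float)
    if np.any(~np.isfinite(Xp)) or np.any(~np.isfinite(Xb)):
        raise ValueError("feature matrices must be finite")
    m, k = Xp.shape
    if m < 10:
        raise ValueError(f"need >= 10 presence rows, got {m}")
    if Xb.shape[0] < 10 * m:
        warnings.warn(
            f"background ({Xb.shape[0]}) smaller than 10x presences ({m}); "
            "expectation estimates may be noisy",
            stacklevel=2,
        )
    if betas is None:
        s = np.maximum(Xp.std(axis=0, ddof=0), 1e-3)
        mult = np.ones(k)
        if feature_kinds is not None:
            cm = {**DEFAULT_CLASS_MULTIPLIERS, **(class_multipliers or {})}
            mult = np.array([cm[kind] for kind in feature_kinds])
        betas = beta_multiplier * mult * s / np.sqrt(m)
    betas = np.asarray(betas, dtype=float)

    Xp_mean = Xp.mean(axis=0)

    def soft(v, thr):
        return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)

    def smooth(v):
        return float(Xp_mean @ v - logsumexp(Xb @ v))

    # monotone accelerated proximal gradient (MFISTA): the accepted iterate
    # never decreases the penalised objective, the momentum point only
    # drives the prox step
    lam = np.zeros(k)
    lam_prev = lam
    z = lam.copy()
    t_k = 1.0
    step = 1.0
    obj = _penalised_objective(lam, Xp_mean, Xb, betas)
    history = [obj]
    converged = False
    for _ in range(max_iter):
        eta = Xb @ z
        log_z = logsumexp(eta)
        q = np.exp(eta - log_z)
        grad = Xp_mean - q @ Xb
        smooth_z = float(Xp_mean @ z - log_z)
        while True:
            u = soft(z + step * grad, step * betas)
            delta = u - z
            smooth_u = smooth(u)
            if smooth_u >= smooth_z + grad @ delta - (delta @ delta) / (2 * step):
                break
            step *= 0.5
            if step < 1e-14:
                u = z
                smooth_u = smooth_z
                break
        u_obj = smooth_u - float(betas @ np.abs(u))
        lam_prev = lam
        if u_obj >= obj:
            lam, new_obj = u, u_obj
        else:
            new_obj = obj  # keep the best iterate: monotone by construction
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        z = lam + (t_k / t_next) * (u - lam) + ((t_k - 1.0) / t_next) * (lam - lam_prev)
        t_k = t_next
        history.append(new_obj)
        if abs(new_obj - obj) < tol and np.array_equal(lam, u):
            converged = True
            obj = new_obj
            break
        obj = new_obj
        step = min(step * 1.5, 1e6)  # let the step grow back between iterations

    eta = Xb @ lam
    log_z = float(logsumexp(eta))
    q = np.exp(eta - log_z)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    if not converged:
        log.warning("MaxEnt fit did not converge in %d iterations", max_iter)
    info = {
        "objective_history": np.array(history),
        "log_partition": log_z,
        "entropy": entropy,
        "converged": converged,
        "betas": betas,
        "seed": seed,
    }
    return lam, info


def train_maxent(
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    classes: list[str] | str = "auto",
    n_hinge_knots: int = 8,
    clamp: ClampSpec | None = None,
    beta_multiplier: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> MaxEntModel:
    """End-to-end fit from raw predictor tables.

    The feature expander is fitted on the training background (normalisers
    and knots), then both tables are expanded and passed to
    :func:`fit_maxent`.  Feature classes default to the presence-count rule
    of :func:`auto_feature_classes`.
    """
    if classes == "auto":
        classes = auto_feature_classes(len(presence_table))
    expander = FeatureExpander(classes, n_hinge_knots).fit(background_table)
    Xp = expander.transform(presence_table)
    Xb = expander.transform(background_table)
    lam, info = fit_maxent(
        Xp,
        Xb,
        beta_multiplier=beta_multiplier,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        feature_kinds=expander.kinds,
    )
    return MaxEntModel(
        expander=expander,
        weights=lam,
        reg_weights=info["betas"],
        clamp=clamp,
        log_partition=info["log_partition"],
        entropy=info["entropy"],
        n_background=len(background_table),
        converged=info["converged"],
        seed=seed,
        objective_history=info["objective_history"],
    )


# ----------------------------------------------------------------------
# prediction


def predict_raw(model: MaxEntModel, env_at_locations: pd.DataFrame) -> np.ndarray:
    """Relative occurrence rate q(x) with training normalisers and log Z.

    Clamping is applied first; over the training background the values sum
    to 1 by construction.
    """
    table = apply_clamp(env_at_locations, model.clamp)
    X = model.expander.transform(table)
    return np.exp(X @ model.weights - model.log_partition)


def to_cloglog(raw: np.ndarray, entropy: float) -> np.ndarray:
    """Complementary log-log suitability: p = 1 - exp(-e^H * raw)."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw[np.isfinite(raw)] < 0):
        raise ValueError("raw values must be >= 0")
    return 1.0 - np.exp(-np.exp(entropy) * raw)


def predict_surface(model: MaxEntModel, stack: EnvStack) -> SuitabilitySurface:
    """Project a fitted model over every land cell of a stack."""
    mask = stack.land_mask()
    table = stack.values_table(mask)[model.variables]
    raw_vals = predict_raw(model, table)
    raw = np.full(stack.grid.shape, np.nan).ravel()
    raw[table.index] = raw_vals
    raw = raw.reshape(stack.grid.shape)
    clog = np.where(mask, to_cloglog(raw, model.entropy), np.nan)
    return SuitabilitySurface(grid=stack.grid, raw=raw, cloglog=clog)


# ----------------------------------------------------------------------
# serialisation: plain-text "lambdas"-style file


def save_model(model: MaxEntModel, path) -> None:
    lines = ["# maxampo maxent model v1"]
    lines.append(f"log_partition={float(model.log_partition)!r}")
    lines.append(f"entropy={float(model.entropy)!r}")
    lines.append(f"n_background={model.n_background}")
    lines.append(f"converged={int(model.converged)}")
    lines.append(f"seed={'' if model.seed is None else model.seed}")
    lines.append(f"classes={','.join(model.expander.classes)}")
    lines.append(f"n_hinge_knots={model.expander.n_hinge_knots}")
    lines.append("[normalisers]")
    for v in model.variables:
        mn, mx = model.expander.normalisers[v]
        lines.append(f"{v}\t{float(mn)!r}\t{float(mx)!r}")
    lines.append("[clamp]")
    if model.clamp is not None:
        for v, (lo, hi) in model.clamp.bounds.items():
            lines.append(f"{v}\t{float(lo)!r}\t{float(hi)!r}")
    lines.append("[features]")
    for spec, lam, beta in zip(model.features, model.weights, model.reg_weights):
        knot = "" if spec.knot is None else repr(float(spec.knot))
        direc = spec.direction or ""
        lines.append(
            f"{spec.kind}\t{'*'.join(spec.variables)}\t{knot}\t{direc}\t"
            f"{float(lam)!r}\t{float(beta)!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path) -> MaxEntModel:
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    sections: dict[str, list[str]] = {"normalisers": [], "clamp": [], "features": []}
    current = None
    for line in text:
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            continue
        if current is None:
            k, _, v = line.partition("=")
            header[k] = v
        else:
            sections[current].append(line)

    expander = FeatureExpander(
        header["classes"].split(","), int(header["n_hinge_knots"])
    )
    normalisers = {}
    variables = []
    for line in sections["normalisers"]:
        v, mn, mx = line.split("\t")
        variables.append(v)
        normalisers[v] = (float(mn), float(mx))
    expander.variables = variables
    expander.normalisers = normalisers
    specs, lams, betas = [], [], []
    for line in sections["features"]:
        kind, vars_, knot, direc, lam, beta = line.split("\t")
        specs.append(
            FeatureSpec(
                kind,
                tuple(vars_.split("*")),
                float(knot) if knot else None,
                direc or None,
            )
        )
        lams.append(float(lam))
        betas.append(float(beta))
    expander.specs = specs
    clamp = None
    if sections["clamp"]:
        bounds = {}
        for line in sections["clamp"]:
            v, lo, hi = line.split("\t")
            bounds[v] = (float(lo), float(hi))
        clamp = ClampSpec(bounds=bounds, quantiles={v: (0.0, 1.0) for v in bounds})
    return MaxEntModel(
        expander=expander,
        weights=np.array(lams),
        reg_weights=np.array(betas),
        clamp=clamp,
        log_partition=float(header["log_partition"]),
        entropy=float(header["entropy"]),
        n_background=int(header["n_background"]),
        converged=bool(int(header["converged"])),
        seed=int(header["seed"]) if header.get("seed") else None,
    )
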