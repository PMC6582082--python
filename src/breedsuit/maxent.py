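"""Maximum-entropy presence-background suitability model.

The model estimates a Gibbs distribution over background cells,
P(x) ∝ exp(λ·f(x)), whose feature expectations match those observed at
presence sites, subject to an L1 penalty.  Fitting minimizes the convex
regularized objective

    J(λ) = −(1/m)·Σ_presences λ·f(xᵢ) + log Σ_background exp(λ·f(x))
           + Σ_k β_k·|λ_k|

with per-feature penalties β_k = reg_multiplier · class_beta(m) ·
sd_k(presence features) / √m, where class_beta(m) is the standard
per-feature-class regularization table (interpolated in the presence
count m).  Optimization is cyclic coordinate descent with a
proximal-Newton step and halving line search per coordinate — robust
for L1 objectives and traceable, so per-feature objective gains can be
attributed for "path" variable contributions.

Raw output is the normalized Gibbs density over background (sums to 1);
logistic output is c·raw/(1 + c·raw) with c = exp(H), H the entropy of
the fitted distribution, which fixes a default prevalence of 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .geodata import OccurrenceSet, RasterStack, points_to_cells

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")

# Per-class regularization constants, interpolated in the presence count.
# These are the reference Maxent/maxnet defaults.
REG_TABLE = {
    "linear": ([0.0, 10.0, 30.0, 100.0], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0.0, 10.0, 17.0, 30.0, 100.0], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0.0, 10.0, 17.0, 30.0, 100.0], [2.6, 1.6, 0.9, 0.55, 0.05]),
    "hinge": ([0.0, 100.0], [0.5, 0.5]),
}


def default_class_beta(feature_class: str, m: int) -> float:
    """Class-specific regularization constant at presence count ``m``."""
    xs, ys = REG_TABLE[feature_class]
    return float(np.interp(float(m), xs, ys))


def default_classes_for(m: int) -> set[str]:
    """Feature classes enabled by presence count, following Maxent practice."""
    if m < 10:
        return {"linear"}
    if m < 15:
        return {"linear", "quadratic"}
    if m < 80:
        return {"linear", "quadratic", "hinge"}
    return {"linear", "quadratic", "product", "hinge"}


@dataclass
class MaxentConfig:
    """Fitting knobs.  ``classes=None`` selects them from the presence count."""

    classes: set[str] | None = None
    n_hinge_knots: int = 10
    reg_multiplier: float = 1.0
    tol: float = 1e-7
    max_iter: int = 500
    background_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reg_multiplier <= 0:
            raise ValueError("reg_multiplier must be > 0")
        if self.classes is not None:
            self.classes = set(self.classes)
            bad = self.classes - set(FEATURE_CLASSES)
            if bad:
                raise ValueError(f"unknown feature classes {sorted(bad)}")
            if not self.classes:
                raise ValueError("classes must be non-empty")


@dataclass
class FeatureExpansion:
    """Feature construction recipe fixed on the background sample.

    Variables are min–max scaled to [0,1] using background extremes;
    every derived feature then lies in [0,1] on the background.
    Variables constant over the background carry no information and are
    dropped (recorded in ``dropped``).
    """

    variable_names: list[str]
    scaling: dict[str, tuple[float, float]]
    classes_used: list[str]
    hinge_knots: dict[str, list[float]]  # knots in scaled [0,1) space
    feature_names: list[str] = field(default_factory=list)
    feature_classes: list[str] = field(default_factory=list)
    feature_vars: list[tuple[str, ...]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self._enumerate_features()

    def _enumerate_features(self) -> None:
        names, classes, fvars = [], [], []
        keep = self.variable_names
        if "linear" in self.classes_used:
            for v in keep:
                names.append(v)
                classes.append("linear")
                fvars.append((v,))
        if "quadratic" in self.classes_used:
            for v in keep:
                names.append(f"{v}^2")
                classes.append("quadratic")
                fvars.append((v,))
        if "product" in self.classes_used:
            for i, a in enumerate(keep):
                for b in keep[i + 1:]:
                    names.append(f"{a}*{b}")
                    classes.append("product")
                    fvars.append((a, b))
        if "hinge" in self.classes_used:
            for v in keep:
                for k in self.hinge_knots.get(v, []):
                    names.append(f"hinge({v},{k:.4g})")
                    classes.append("hinge")
                    fvars.append((v,))
                for k in self.hinge_knots.get(v, []):
                    if k > 0:
                        names.append(f"rhinge({v},{k:.4g})")
                        classes.append("hinge")
                        fvars.append((v,))
        self.feature_names = names
        self.feature_classes = classes
        self.feature_vars = fvars

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def scale_variables(self, covariates: np.ndarray,
                        all_names: list[str] | None = None) -> np.ndarray:
        """Min–max scale (and clamp) raw covariate columns to [0,1]."""
        all_names = all_names or self.variable_names
        cols = []
        for v in self.variable_names:
            j = all_names.index(v)
            lo, hi = self.scaling[v]
            cols.append(np.clip((covariates[:, j] - lo) / (hi - lo), 0.0, 1.0))
        return np.column_stack(cols) if cols else np.empty((covariates.shape[0], 0))

    def transform(self, covariates: np.ndarray,
                  all_names: list[str] | None = None) -> np.ndarray:
        """Raw covariate matrix → feature matrix (clamped to training range)."""
        scaled = self.scale_variables(np.atleast_2d(covariates), all_names)
        col = {v: scaled[:, i] for i, v in enumerate(self.variable_names)}
        feats = np.empty((scaled.shape[0], self.n_features))
        for k, (name, cls, fv) in enumerate(
                zip(self.feature_names, self.feature_classes, self.feature_vars)):
            if cls == "linear":
                feats[:, k] = col[fv[0]]
            elif cls == "quadratic":
                feats[:, k] = col[fv[0]] ** 2
            elif cls == "product":
                feats[:, k] = col[fv[0]] * col[fv[1]]
            else:  # hinge / reverse hinge, knot recoverable from the name
                knot = float(name[name.index(",") + 1:-1])
                if name.startswith("rhinge"):
                    feats[:, k] = np.maximum(0.0, (knot - col[fv[0]]) / knot)
                else:
                    feats[:, k] = np.maximum(0.0, (col[fv[0]] - knot) / (1.0 - knot))
        return feats


def build_features(covariates: np.ndarray, classes: set[str],
                   n_hinge_knots: int = 10,
                   variable_names: list[str] | None = None) -> FeatureExpansion:
    """Fix scaling and knots on a background sample and enumerate features.

    Hinge knots sit at j/n_hinge_knots (j = 0..n−1) of the scaled range
    for forward hinges, with reverse hinges at the interior knots.
    """
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[1] < 1:
        raise ValueError("need at least one covariate")
    classes = set(classes)
    if not classes or classes - set(FEATURE_CLASSES):
        raise ValueError(f"classes must be a non-empty subset of {FEATURE_CLASSES}")
    if variable_names is None:
        variable_names = [f"var{i + 1}" for i in range(covariates.shape[1])]
    lo = covariates.min(axis=0)
    hi = covariates.max(axis=0)
    keep = [v for j, v in enumerate(variable_names) if hi[j] > lo[j]]
    dropped = [v for v in variable_names if v not in keep]
    if not keep:
        raise ValueError("all covariates are constant over the background")
    scaling = {v: (float(lo[variable_names.index(v)]),
                   float(hi[variable_names.index(v)])) for v in keep}
    knots = {}
    if "hinge" in classes:
        base = [j / n_hinge_knots for j in range(n_hinge_knots)]
        knots = {v: base for v in keep}
    exp = FeatureExpansion(variable_names=keep, scaling=scaling,
                           classes_used=sorted(classes), hinge_knots=knots,
                           dropped=dropped)
    return exp


@dataclass
class MaxentModel:
    """A fitted model: feature weights plus everything needed to predict."""

    lambdas: np.ndarray
    expansion: FeatureExpansion
    log_Z: float
    entropy_H: float
    reg_betas: np.ndarray
    presence_count: int
    objective_value: float
    converged: bool
    n_background: int
    path_gain: np.ndarray | None = None
    breed: str = ""

    def raw_scores(self, covariates: np.ndarray,
                   all_names: list[str] | None = None) -> np.ndarray:
        """Unnormalized log-density λ·f(x) for rows of a covariate matrix."""
        F = self.expansion.transform(covariates, all_names)
        return F @ self.lambdas

    def predict_values(self, covariates: np.ndarray, scale: str = "logistic",
                       all_names: list[str] | None = None) -> np.ndarray:
        """Raw or logistic suitability for rows of a covariate matrix."""
        s = self.raw_scores(covariates, all_names)
        raw = np.exp(s - self.log_Z)
        if scale == "raw":
            return raw
        if scale == "logistic":
            c = np.exp(self.entropy_H)
            return c * raw / (1.0 + c * raw)
        raise ValueError(f"unknown scale {scale!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "lambdas": self.lambdas.tolist(),
            "log_Z": self.log_Z,
            "entropy_H": self.entropy_H,
            "reg_betas": self.reg_betas.tolist(),
            "presence_count": self.presence_count,
            "objective_value": self.objective_value,
            "converged": self.converged,
            "n_background": self.n_background,
            "breed": self.breed,
            "expansion": asdict(self.expansion),
        }
        if self.path_gain is not None:
            d["path_gain"] = self.path_gain.tolist()
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        ed = d["expansion"]
        exp = FeatureExpansion(
            variable_names=list(ed["variable_names"]),
            scaling={k: tuple(v) for k, v in ed["scaling"].items()},
            classes_used=list(ed["classes_used"]),
            hinge_knots={k: list(v) for k, v in ed["hinge_knots"].items()},
            feature_names=list(ed["feature_names"]),
            feature_classes=list(ed["feature_classes"]),
            feature_vars=[tuple(t) for t in ed["feature_vars"]],
            dropped=list(ed.get("dropped", [])),
        )
        return cls(
            lambdas=np.asarray(d["lambdas"], dtype=float),
            expansion=exp,
            log_Z=float(d["log_Z"]),
            entropy_H=float(d["entropy_H"]),
            reg_betas=np.asarray(d["reg_betas"], dtype=float),
            presence_count=int(d["presence_count"]),
            objective_value=float(d["objective_value"]),
            converged=bool(d["converged"]),
            n_background=int(d["n_background"]),
            path_gain=(np.asarray(d["path_gain"], dtype=float)
                       if "path_gain" in d else None),
            breed=d.get("breed", ""),
        )

    @classmethod
    def load(cls, path) -> "MaxentModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def regularized_objective(lam: np.ndarray, F_bg: np.ndarray,
                          pbar: np.ndarray, betas: np.ndarray) -> float:
    """J(λ) = −λ·p̄ + log Σ_bg exp(λ·f) + Σ β|λ| (p̄ = presence feature means)."""
    lam = np.asarray(lam, dtype=float)
    return float(-lam @ pbar + logsumexp(F_bg @ lam) + betas @ np.abs(lam))


def _soft_threshold(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def fit_maxent(presence_covariates: np.ndarray,
               background_covariates: np.ndarray,
               config: MaxentConfig | None = None,
               variable_names: list[str] | None = None,
               breed: str = "") -> MaxentModel:
    """Fit λ by cyclic proximal-Newton coordinate descent on J(λ).

    Each coordinate takes a soft-thresholded Newton step using the
    fitted distribution's feature mean and variance, backed by a halving
    line search that guarantees monotone objective decrease.  Converged
    means the objective fell by less than ``tol`` over one full sweep
    before ``max_iter`` sweeps; otherwise ``converged=False`` is
    reported (never an exception).
    """
    config = config or MaxentConfig()
    P = np.atleast_2d(np.asarray(presence_covariates, dtype=float))
    B = np.atleast_2d(np.asarray(background_covariates, dtype=float))
    if P.shape[0] < 1:
        raise ValueError("need at least one presence row")
    if B.shape[0] < 2:
        raise ValueError("need at least two background cells")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(B))):
        raise ValueError("covariates must be finite")
    m = P.shape[0]
    classes = config.classes if config.classes is not None else default_classes_for(m)
    if variable_names is None:
        variable_names = [f"var{i + 1}" for i in range(B.shape[1])]

    expansion = build_features(B, classes, config.n_hinge_knots, variable_names)
    F = expansion.transform(B, variable_names)       # background × features
    Fp = expansion.transform(P, variable_names)      # presences × features
    K = expansion.n_features
    pbar = Fp.mean(axis=0)

    sd = Fp.std(axis=0, ddof=1) if m > 1 else np.zeros(K)
    sd = np.maximum(sd, 1e-6)  # numerical guard against a free coordinate
    class_beta = np.array([default_class_beta(c, m)
                           for c in expansion.feature_classes])
    betas = config.reg_multiplier * class_beta * sd / np.sqrt(m)

    lam = np.zeros(K)
    s = np.zeros(F.shape[0])          # cached background scores F @ lam
    lse = logsumexp(s)
    J = float(-lam @ pbar + lse + betas @ np.abs(lam))
    gain = np.zeros(K)
    converged = False

    for _ in range(config.max_iter):
        J_start = J
        for k in range(K):
            fk = F[:, k]
            w = np.exp(s - lse)       # fitted distribution over background
            mu = w @ fk
            var = w @ (fk * fk) - mu * mu
            grad = -pbar[k] + mu
            h = max(var, 1e-12)
            target = _soft_threshold(lam[k] - grad / h, betas[k] / h)
            delta = target - lam[k]
            if delta == 0.0:
                continue
            step = 1.0
            for _ls in range(40):
                cand = lam[k] + step * delta
                s_try = s + step * delta * fk
                lse_try = logsumexp(s_try)
                J_try = (J + lam[k] * pbar[k] - cand * pbar[k]
                         + lse_try - lse
                         + betas[k] * (abs(cand) - abs(lam[k])))
                if J_try < J:
                    gain[k] += J - J_try
                    lam[k] = cand
                    s = s_try
                    lse = lse_try
                    J = J_try
                    break
                step *= 0.5
        if J_start - J < config.tol:
            converged = True
            break

    log_Z = lse
    raw = np.exp(s - log_Z)
    entropy_H = float(log_Z - raw @ s)
    return MaxentModel(
        lambdas=lam, expansion=expansion, log_Z=float(log_Z),
        entropy_H=entropy_H, reg_betas=betas, presence_count=m,
        objective_value=float(J), converged=converged,
        n_background=B.shape[0], path_gain=gain, breed=breed,
    )


@dataclass
class SuitabilityMap:
    """Predicted suitability grid on a stack's geometry."""

    values: np.ndarray
    scale: str
    breed: str = ""
    model_tag: str = ""

    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def predict(model: MaxentModel, stack: RasterStack,
            scale: str = "logistic") -> SuitabilityMap:
    """Suitability surface over a stack's non-missing cells.

    Covariates outside the training [min, max] are clamped to the bounds
    before feature evaluation, so extrapolation beyond the background
    range saturates rather than exploding.
    """
    missing_vars = [v for v in model.expansion.variable_names
                    if v not in stack.layers]
    if missing_vars:
        raise KeyError(f"stack lacks model covariate layers {missing_vars}")
    rows, cols = stack.valid_indices()
    covs = np.column_stack(
        [stack.layers[v][rows, cols] for v in model.expansion.variable_names])
    vals = model.predict_values(covs, scale=scale,
                                all_names=model.expansion.variable_names)
    grid = np.full(stack.shape, np.nan)
    grid[rows, cols] = vals
    return SuitabilityMap(values=grid, scale=scale, breed=model.breed,
                          model_tag=f"maxent(m={model.presence_count})")


def fit_occurrence_model(stack: RasterStack, occurrences: OccurrenceSet,
                         config: MaxentConfig | None = None) -> MaxentModel:
    """Fit from a stack and presence points (the tool's main entry point).

    Presences are deduplicated to one per raster cell; the background is
    every non-missing cell, or a seeded uniform sample of
    ``config.background_size`` cells when the stack is larger.
    """
    config = config or MaxentConfig()
    row, col, kept = points_to_cells(stack, occurrences)
    if kept.size == 0:
        raise ValueError("no occurrence points fall on usable stack cells")
    cells = np.unique(np.column_stack([row, col]), axis=0)
    if cells.shape[0] == 1:
        warnings.warn("all presences fall in a single raster cell; "
                      "the fit is degenerate but proceeds")
    names = stack.layer_names
    P = np.column_stack([stack.layers[v][cells[:, 0], cells[:, 1]] for v in names])
    rows_b, cols_b = stack.valid_indices()
    if rows_b.size > config.background_size:
        rng = np.random.default_rng(config.seed)
        pick = rng.choice(rows_b.size, size=config.background_size, replace=False)
        rows_b, cols_b = rows_b[pick], cols_b[pick]
    B = np.column_stack([stack.layers[v][rows_b, cols_b] for v in names])
    return fit_maxent(P, B, config, variable_names=names,
                      breed=occurrences.breed)


@dataclass
class ContributionTable:
    """Per-variable percent contributions (one method per table)."""

    method: str
    rows: list[tuple[str, float]]  # (variable, percent), sorted descending

    def as_dict(self) -> dict[str, float]:
        return dict(self.rows)

    def top(self, n: int) -> list[str]:
        return [v for v, _ in self.rows[:n]]


def variable_contributions(model: MaxentModel,
                           presence_covariates: np.ndarray,
                           background_covariates: np.ndarray,
                           method: str = "permutation",
                           n_repeats: int = 5, seed: int = 0,
                           variable_names: list[str] | None = None
                           ) -> ContributionTable:
    """Percent contribution of each covariate to the fitted model.

    ``permutation``: permute one variable's values jointly across the
    concatenated presence+background rows (a single shared permutation,
    preserving the rows' split), recompute the presence-vs-background
    AUC, and average the AUC drop over repeats; drops are floored at 0
    and normalized to sum to 100%.  ``path``: per-feature objective
    gains accumulated during coordinate descent are aggregated to their
    source variables (product features split evenly between their two
    parents) and normalized to 100%.
    """
    from .evaluate import roc_auc  # local import to avoid a module cycle

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    exp = model.expansion
    if variable_names is None:
        variable_names = exp.variable_names
    P = np.atleast_2d(np.asarray(presence_covariates, dtype=float))
    B = np.atleast_2d(np.asarray(background_covariates, dtype=float))

    if method == "path":
        if model.path_gain is None:
            raise ValueError("model carries no optimization path record")
        shares = {v: 0.0 for v in exp.variable_names}
        for g, fv in zip(model.path_gain, exp.feature_vars):
            for v in fv:
                shares[v] += max(g, 0.0) / len(fv)
        raw = np.array([shares[v] for v in exp.variable_names])
    elif method == "permutation":
        X = np.vstack([P, B])
        n_p = P.shape[0]
        base_sp = model.raw_scores(P, variable_names)
        base_sb = model.raw_scores(B, variable_names)
        base_auc = roc_auc(base_sp, base_sb)
        rng = np.random.default_rng(seed)
        drops = []
        for v in exp.variable_names:
            j = variable_names.index(v)
            d = 0.0
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
                sp = model.raw_scores(Xp[:n_p], variable_names)
                sb = model.raw_scores(Xp[n_p:], variable_names)
                d += base_auc - roc_auc(sp, sb)
            drops.append(max(d / n_repeats, 0.0))
        raw = np.array(drops)
    else:
        raise ValueError(f"unknown method {method!r}")

    total = raw.sum()
    if total <= 0:  # no variable moves the model: report an even split
        pct = np.full(raw.size, 100.0 / raw.size)
    else:
        pct = 100.0 * raw / total
    rows = sorted(zip(exp.variable_names, pct.tolist()),
                  key=lambda t: (-t[1], t[0]))
    return ContributionTable(method=method, rows=rows)
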