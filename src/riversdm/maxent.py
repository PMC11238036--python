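"""Maximum-entropy presence-background habitat model, from scratch.

Fits a Gibbs distribution over environmental features whose expectations
match presence data, with L1 (lasso) regularization — the estimator behind
MaxEnt.  The penalized log-likelihood

    sum_presences [lambda . f(x) - log Z] - sum_j beta_j |lambda_j|,
    Z = sum_background exp(lambda . f)

is concave; it is maximized by L-BFGS-B on a positive/negative split of
lambda, which handles the L1 term exactly and yields exact zeros at the
bound.  Output transforms follow MaxEnt 3.4.4: raw (normalized over
background), logistic, and the default cloglog.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "FeatureDef",
    "FeatureSet",
    "MaxentModel",
    "ConvergenceError",
    "build_features",
    "fit_maxent",
    "predict",
    "maxent_aicc",
    "default_class_scale",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

# Published MaxEnt default regularization scales.  Linear/quadratic/product
# interpolate on presence count; hinge and threshold are constant.
_LQP_TABLE = [(10, 1.0), (30, 0.2), (100, 0.05)]


def default_class_scale(feature_class: str, n_presences: int) -> float:
    if feature_class == "hinge":
        return 0.5
    if feature_class == "threshold":
        return 1.0
    pts = _LQP_TABLE
    if n_presences <= pts[0][0]:
        return pts[0][1]
    if n_presences >= pts[-1][0]:
        return pts[-1][1]
    for (n0, s0), (n1, s1) in zip(pts[:-1], pts[1:]):
        if n0 <= n_presences <= n1:
            t = (n_presences - n0) / (n1 - n0)
            return s0 + t * (s1 - s0)
    return pts[-1][1]


class ConvergenceError(RuntimeError):
    def __init__(self, gap: float):
        super().__init__(f"maxent solver did not converge (last gap {gap:.3e})")
        self.gap = gap


@dataclass
class FeatureDef:
    name: str
    feature_class: str
    predictors: tuple[str, ...]
    knot: float | None = None  # on the [0,1] scaled axis


@dataclass
class FeatureSet:
    """Feature definitions plus background min-max scaling per predictor."""

    defs: list[FeatureDef]
    scaling: dict[str, tuple[float, float]]  # predictor -> (min, max) on background

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def classes_used(self) -> set[str]:
        return {d.feature_class for d in self.defs}

    def _scaled(self, table: pd.DataFrame, clamp: bool) -> dict[str, np.ndarray]:
        out = {}
        clamped_any = False
        for p, (lo, hi) in self.scaling.items():
            u = (table[p].to_numpy(dtype=float) - lo) / (hi - lo)
            if clamp:
                if ((u < -1e-12) | (u > 1 + 1e-12)).any():
                    clamped_any = True
                u = np.clip(u, 0.0, 1.0)
            out[p] = u
        if clamped_any:
            warnings.warn("predictor values outside training range clamped to [0, 1]")
        return out

    def transform(self, table: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """Feature matrix (rows x features), all values in [0, 1]."""
        u = self._scaled(table, clamp)
        cols = []
        for d in self.defs:
            if d.feature_class == "linear":
                cols.append(u[d.predictors[0]])
            elif d.feature_class == "quadratic":
                cols.append(u[d.predictors[0]] ** 2)
            elif d.feature_class == "product":
                cols.append(u[d.predictors[0]] * u[d.predictors[1]])
            elif d.feature_class == "hinge":
                x = u[d.predictors[0]]
                t = d.knot
                if d.name.startswith("rhinge"):
                    cols.append(np.maximum(0.0, (t - x) / t))
                else:
                    cols.append(np.maximum(0.0, (x - t) / (1.0 - t)))
            elif d.feature_class == "threshold":
                cols.append((u[d.predictors[0]] > d.knot).astype(float))
            else:  # pragma: no cover
                raise ValueError(d.feature_class)
        return np.column_stack(cols) if cols else np.empty((len(table), 0))


def build_features(
    background: pd.DataFrame,
    classes: str | set[str] = "lq",
    knots_per_hinge: int = 5,
    predictors: list[str] | None = None,
) -> FeatureSet:
    """Expand requested feature classes over a background predictor table.

    ``classes`` is either a set of class names or a compact code using
    MaxEnt letters (l, q, p, h, t).  Hinge knots sit at equally spaced
    background quantiles; constant predictors are dropped with a warning.
    """
    if isinstance(classes, str):
        letter = {"l": "linear", "q": "quadratic", "p": "product",
                  "h": "hinge", "t": "threshold"}
        classes = {letter[ch] for ch in classes}
    unknown = classes - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}")
    if len(background) < 2:
        raise ValueError("need at least 2 background points")
    predictors = list(predictors or background.columns)
    scaling: dict[str, tuple[float, float]] = {}
    for p in predictors:
        x = background[p].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo <= 0:
            warnings.warn(f"constant predictor '{p}' dropped from features")
            continue
        scaling[p] = (lo, hi)
    kept = [p for p in predictors if p in scaling]
    if not kept:
        raise ValueError("no non-constant predictors")

    defs: list[FeatureDef] = []
    for p in kept:
        if "linear" in classes:
            defs.append(FeatureDef(f"lin({p})", "linear", (p,)))
    for p in kept:
        if "quadratic" in classes:
            defs.append(FeatureDef(f"quad({p})", "quadratic", (p,)))
    if "product" in classes:
        for i, p in enumerate(kept):
            for q in kept[i + 1:]:
                defs.append(FeatureDef(f"prod({p},{q})", "product", (p, q)))
    if "hinge" in classes or "threshold" in classes:
        qs = np.linspace(0, 1, knots_per_hinge + 2)[1:-1]
        for p in kept:
            lo, hi = scaling[p]
            u = np.clip(
                (background[p].to_numpy(dtype=float) - lo) / (hi - lo), 0, 1
            )
            knots = np.quantile(u, qs)
            for k, t in enumerate(knots):
                if not (0.0 < t < 1.0):
                    continue
                if "hinge" in classes:
                    defs.append(FeatureDef(f"hinge({p},{k})", "hinge", (p,), float(t)))
                    defs.append(FeatureDef(f"rhinge({p},{k})", "hinge", (p,), float(t)))
                if "threshold" in classes:
                    defs.append(FeatureDef(f"thr({p},{k})", "threshold", (p,), float(t)))
    return FeatureSet(defs=defs, scaling=scaling)


@dataclass
class MaxentModel:
    """Fitted Gibbs model: weights, normalizer and output-transform state."""

    features: FeatureSet
    lambdas: np.ndarray
    beta: float
    feature_betas: np.ndarray
    log_z: float                 # log normalizer over training background
    entropy: float               # H of the raw distribution over background
    transform: str = "cloglog"
    objective_history: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    def n_parameters(self, tol: float = 1e-7) -> int:
        return int((np.abs(self.lambdas) > tol).sum())

    def raw(self, table: pd.DataFrame) -> np.ndarray:
        f = self.features.transform(table)
        return np.exp(f @ self.lambdas - self.log_z)

    def to_lambdas_text(self) -> str:
        lines = []
        for d, lam in zip(self.features.defs, self.lambdas):
            lo, hi = self.features.scaling[d.predictors[0]]
            lines.append(f"{d.name}, {lam:.10g}, {lo:.10g}, {hi:.10g}")
        return "\n".join(lines) + "\n"

    def header_json(self) -> str:
        return json.dumps({
            "beta": self.beta,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "transform": self.transform,
            "n_features": len(self.lambdas),
        }, indent=2)


def fit_maxent(
    features: FeatureSet,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    beta: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MaxentModel:
    """Maximize the L1-penalized Gibbs log-likelihood.

    beta_j = beta * scale(class_j, n_presences) * sd_background(f_j) /
    sqrt(n_presences).  Convex; L-BFGS-B on the positive/negative split of
    lambda converges to relative objective change < tol or raises after
    max_iter iterations.
    """
    if len(presences) < 2:
        raise ValueError("need at least 2 presences")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    fp = features.transform(presences)
    fb = features.transform(background, clamp=False)
    n, k = fp.shape
    if k == 0:
        raise ValueError("feature set is empty")
    sd = fb.std(axis=0)
    scales = np.array([
        default_class_scale(d.feature_class, n) for d in features.defs
    ])
    betas = beta * scales * sd / np.sqrt(n)

    sum_fp = fp.sum(axis=0)
    history: list[float] = []

    def neg_objective(theta):
        lam = theta[:k] - theta[k:]
        eta = fb @ lam
        lz = logsumexp(eta)
        obj = sum_fp @ lam - n * lz - betas @ (theta[:k] + theta[k:])
        # gradient of the NEGATIVE objective
        p = np.exp(eta - lz)
        e_f = p @ fb
        g_lam = sum_fp - n * e_f
        grad = np.concatenate([-g_lam + betas, g_lam + betas])
        history.append(-obj)
        return -obj, grad

    theta0 = np.zeros(2 * k)
    res = minimize(
        neg_objective, theta0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": 1e-9,
                 "maxfun": 10 * max_iter * (2 * k + 1)},
    )
    lam = res.x[:k] - res.x[k:]
    if not res.success and "ITERATIONS" in str(res.message).upper():
        gap = abs(history[-1] - history[-2]) if len(history) > 1 else np.inf
        if len(history) > 1 and gap > tol * max(1.0, abs(history[-1])):
            raise ConvergenceError(gap)

    eta_b = fb @ lam
    log_z = float(logsumexp(eta_b))
    p = np.exp(eta_b - log_z)
    entropy = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())
    # record the best objective seen at each evaluation (monotone envelope of
    # the line-searched iterates)
    mono = list(np.minimum.accumulate(history))
    return MaxentModel(
        features=features, lambdas=lam, beta=beta, feature_betas=betas,
        log_z=log_z, entropy=entropy, objective_history=mono,
        converged=bool(res.success),
    )


def predict(
    model: MaxentModel, table: pd.DataFrame, transform: str | None = None
) -> np.ndarray:
    """Suitability per row: raw, logistic, or cloglog (3.4.4 default)."""
    transform = transform or model.transform
    r = model.raw(table)
    if transform == "raw":
        return r
    s = r * np.exp(model.entropy)
    if transform == "logistic":
        return s / (1.0 + s)
    if transform == "cloglog":
        return 1.0 - np.exp(-s)
    raise ValueError(f"unknown transform '{transform}'")


def maxent_aicc(
    model: MaxentModel, presences: pd.DataFrame, background: pd.DataFrame
) -> float:
    """MaxEnt-style AICc: raw likelihood at presences, k = non-zero weights.

    Returns NaN (candidate invalid) when n_presences <= k + 1.
    """
    k = model.n_parameters()
    n = len(presences)
    if n <= k + 1:
        return float("nan")
    fp = model.features.transform(presences)
    fb = model.features.transform(background, clamp=False)
    log_z = logsumexp(fb @ model.lambdas)
    lnl = float((fp @ model.lambdas - log_z).sum())
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
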