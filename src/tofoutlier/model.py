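"""Cost-sensitive L2-regularized logistic regression (CSLR).

Class imbalance (~5.6% outliers) is handled by weighting the per-sample
log-likelihood terms: errors on the rare (outlier) class cost more than
errors on the normal class.  The fitted objective is the weighted penalized
negative log-likelihood

    J(b0, b) = - sum_i w_{y_i} [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
               + lambda ||b||^2,      p_i = sigmoid(b . x_i + b0),

with the intercept excluded from the penalty.  Minimization uses L-BFGS-B
with the analytic gradient, starting from zero coefficients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ValidationError

_LOG_EPS = 1e-12  # probability clipping for log terms


@dataclass
class CSLRConfig:
    class_weights: Tuple[float, float] = (1.0, 1.0)  # (w_normal, w_outlier)
    l2_lambda: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-8  # convergence tolerance on objective change
    threshold: float = 0.5
    standardize: bool = True
    # "robust" (median/IQR) or "zscore"; robust centering keeps the rare
    # class's extreme feature values from inflating the scale estimate
    scaling: str = "robust"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.class_weights) <= 0:
            raise ValidationError("class weights must be strictly positive")
        if self.l2_lambda < 0:
            raise ValidationError("l2_lambda must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must lie in (0, 1)")
        if self.scaling not in ("robust", "zscore"):
            raise ValidationError("scaling must be 'robust' or 'zscore'")

    def replace(self, **kw) -> "CSLRConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class FittedCSLR:
    beta: np.ndarray
    beta0: float
    feature_names: List[str]
    scaler: List[Tuple[float, float]]  # per-feature (center, scale)
    config: CSLRConfig
    converged: bool
    final_objective: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not (len(self.beta) == len(self.feature_names) == len(self.scaler)):
            raise ValidationError("beta, feature_names and scaler lengths differ")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "beta": self.beta.tolist(),
                "beta0": self.beta0,
                "scaler": [list(cs) for cs in self.scaler],
                "config": dataclasses.asdict(self.config),
                "converged": self.converged,
                "final_objective": self.final_objective,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedCSLR":
        d = json.loads(text)
        cfg = d["config"]
        cfg["class_weights"] = tuple(cfg["class_weights"])
        return cls(
            beta=np.array(d["beta"], dtype=float),
            beta0=float(d["beta0"]),
            feature_names=list(d["feature_names"]),
            scaler=[tuple(cs) for cs in d["scaler"]],
            config=CSLRConfig(**cfg),
            converged=bool(d["converged"]),
            final_objective=float(d["final_objective"]),
        )


def _as_matrix(X, feature_names: Optional[List[str]] = None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise ValidationError(f"missing feature columns: {missing}")
            X = X[feature_names]
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-dimensional")
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cslr_objective(
    beta: np.ndarray, beta0: float, X: np.ndarray, y: np.ndarray, config: CSLRConfig
) -> float:
    """Weighted penalized negative log-likelihood (intercept unpenalized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValidationError("X row count must equal y length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("y must be binary 0/1")
    w = np.where(y == 1, config.class_weights[1], config.class_weights[0])
    p = np.clip(_sigmoid(X @ np.asarray(beta, dtype=float) + beta0), _LOG_EPS, 1 - _LOG_EPS)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-np.sum(w * ll) + config.l2_lambda * np.dot(beta, beta))


def cslr_gradient(
    beta: np.ndarray, beta0: float, X: np.ndarray, y: np.ndarray, config: CSLRConfig
):
    """Analytic gradient of :func:`cslr_objective` w.r.t. (beta, beta0)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.where(y == 1, config.class_weights[1], config.class_weights[0])
    p = _sigmoid(X @ np.asarray(beta, dtype=float) + beta0)
    r = w * (p - y)
    g_beta = X.T @ r + 2.0 * config.l2_lambda * np.asarray(beta, dtype=float)
    return g_beta, float(np.sum(r))


def fit(X, y, config: Optional[CSLRConfig] = None, feature_names=None) -> FittedCSLR:
    """Fit the CSLR by quasi-Newton minimization of the weighted objective.

    Features are optionally standardized on training statistics (robust
    median/IQR by default, classical z-scoring via ``config.scaling``);
    the scaler is stored in the model and re-applied at prediction time.
    """
    config = config or CSLRConfig()
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValidationError("X row count must equal y length")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) < 2:
        raise ValidationError("y must contain both classes 0 and 1")

    if config.standardize:
        if config.scaling == "robust":
            center = np.median(X, axis=0)
            q75, q25 = np.percentile(X, [75, 25], axis=0)
            scale = (q75 - q25) / 1.349  # IQR on the normal-deviate scale
            fallback = X.std(axis=0)
            scale[scale == 0] = fallback[scale == 0]
        else:
            center = X.mean(axis=0)
            scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        center = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - center) / scale

    def fun(theta):
        return cslr_objective(theta[1:], theta[0], Xs, y, config)

    def jac(theta):
        g_beta, g0 = cslr_gradient(theta[1:], theta[0], Xs, y, config)
        return np.concatenate([[g0], g_beta])

    theta0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        fun,
        theta0,
        jac=jac,
        method="L-BFGS-B",
        options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-10},
    )
    return FittedCSLR(
        beta=res.x[1:],
        beta0=float(res.x[0]),
        feature_names=names,
        scaler=list(zip(center.tolist(), scale.tolist())),
        config=config,
        converged=bool(res.success),
        final_objective=float(res.fun),
    )


def predict_proba(model: FittedCSLR, X) -> np.ndarray:
    """Outlier probability per row (stored scaler + logistic link)."""
    X, names = _as_matrix(X, model.feature_names)
    if isinstance(names, list) and names != model.feature_names:
        if len(names) != len(model.feature_names):
            raise ValidationError("feature column mismatch")
    if X.shape[1] != len(model.feature_names):
        raise ValidationError("feature column mismatch")
    center = np.array([c for c, _ in model.scaler])
    scale = np.array([s for _, s in model.scaler])
    Xs = (X - center) / scale
    return _sigmoid(Xs @ model.beta + model.beta0)


def classify(model: FittedCSLR, X) -> np.ndarray:
    """Binary outlier call: 1 iff probability >= config.threshold."""
    return (predict_proba(model, X) >= model.config.threshold).astype(int)
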