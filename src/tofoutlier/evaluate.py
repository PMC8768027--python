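"""Imbalance-aware evaluation protocol for the TOF outlier models.

Implements the full study protocol: a stratified 60/40 train/test split,
stratified 5-fold cross-validated grid search over the L2 strength and the
class-weight ratio, precision/recall/F1 and rank-based ROC-AUC with
stratified percentile-bootstrap confidence intervals, learning curves, and
a Wilcoxon signed-rank comparison of paired per-fold scores.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import model as cslr
from .errors import ValidationError
from .features import BASIC_FEATURES, ENGINEERED_FEATURES

FEATURE_SETS = {"basic": BASIC_FEATURES, "engineered": ENGINEERED_FEATURES}


@dataclass
class SplitSpec:
    test_fraction: float = 0.40
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must lie in (0, 1)")


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec, label_col: str = "label"
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified train/test split.

    The test set holds ceil(n * test_fraction) rows; per-class test counts
    are allocated proportionally with largest-remainder rounding (classes
    ordered by size, largest first, for deterministic tie-breaks).
    """
    n = len(table)
    labels = table[label_col].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if spec.stratified and np.any(counts < 2):
        raise ValidationError("every class needs >= 2 members for a stratified split")
    n_test = math.ceil(n * spec.test_fraction)
    rng = np.random.default_rng(spec.seed)
    test_idx: List[int] = []
    if spec.stratified:
        order = np.argsort(-counts, kind="stable")
        classes, counts = classes[order], counts[order]
        per_class = _largest_remainder(counts * spec.test_fraction, n_test)
        for cls, k in zip(classes, per_class):
            members = np.flatnonzero(labels == cls)
            pick = rng.permutation(members)[:k]
            test_idx.extend(pick.tolist())
    else:
        test_idx = rng.permutation(n)[:n_test].tolist()
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return table.iloc[~mask].copy(), table.iloc[mask].copy()


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def precision_recall_f1(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """ROC-AUC by the Mann-Whitney rank formulation (ties count 1/2)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined without both classes")
    ranks = rankdata(y_score)
    u = np.sum(ranks[y_true == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def metrics(
    y_true, y_pred, y_score=None
) -> Dict[str, object]:
    """Confusion counts, precision, recall, F1 and (if scored) ROC-AUC."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred lengths differ")
    tp, fp, fn, tn = _confusion(y_true, y_pred)
    precision, recall, f1 = precision_recall_f1(tp, fp, fn)
    out: Dict[str, object] = {
        "confusion": {"TP": tp, "FP": fp, "FN": fn, "TN": tn},
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n": int(len(y_true)),
        "n_outliers": int(np.sum(y_true == 1)),
    }
    if y_score is not None:
        out["roc_auc"] = rank_auc(y_true, np.asarray(y_score, dtype=float))
    return out


def roc_curve(y_true, y_score) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, thresholds): one point per distinct threshold.

    Monotone in both coordinates with endpoints (0,0) and (1,1); the
    trapezoidal area equals :func:`rank_auc` to numerical precision.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC undefined without both classes")
    order = np.argsort(-y_score, kind="stable")
    ys, ts = y_true[order], y_score[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    distinct = np.r_[np.flatnonzero(np.diff(ts) != 0), len(ts) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, ts[distinct]]
    return fpr, tpr, thresholds


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def bootstrap_ci(
    y_true,
    y_score_or_pred,
    metric: Callable[[np.ndarray, np.ndarray], float],
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Stratified percentile bootstrap CI for a metric of (y_true, y_hat).

    Rows are resampled with replacement within each class; replicates on
    which the metric is undefined are dropped (and must not be all of them).
    """
    if reps < 100:
        raise ValidationError("reps must be >= 100")
    y_true = np.asarray(y_true).astype(int)
    y_hat = np.asarray(y_score_or_pred, dtype=float)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y_true == 1)
    neg = np.flatnonzero(y_true == 0)
    vals = []
    n_undefined = 0
    for _ in range(reps):
        idx = np.concatenate(
            [
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True),
            ]
        )
        try:
            vals.append(metric(y_true[idx], y_hat[idx]))
        except (ValidationError, ZeroDivisionError):
            n_undefined += 1
    if not vals:
        raise ValidationError("metric undefined on every bootstrap replicate")
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def f1_metric(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp, fp, fn, _ = _confusion(np.asarray(y_true), np.asarray(y_pred) >= 0.5)
    return precision_recall_f1(tp, fp, fn)[2]


def precision_metric(y_true, y_pred) -> float:
    tp, fp, fn, _ = _confusion(np.asarray(y_true), np.asarray(y_pred) >= 0.5)
    return precision_recall_f1(tp, fp, fn)[0]


def recall_metric(y_true, y_pred) -> float:
    tp, fp, fn, _ = _confusion(np.asarray(y_true), np.asarray(y_pred) >= 0.5)
    return precision_recall_f1(tp, fp, fn)[1]


def default_grid(n_normal: int, n_outlier: int) -> List[Tuple[float, float]]:
    """(l2_lambda, w_outlier) grid; w_normal is fixed at 1.

    The weight axis is spaced finely at the low end: with ~5% outliers the
    F1-optimal operating point usually sits between no weighting and the
    inverse-prevalence weight.
    """
    ratios = sorted({1.0, 2.0, 3.0, 5.0, 8.0, 12.0, n_normal / n_outlier, 25.0})
    return [(lam, r) for lam in (0.01, 0.1, 1.0, 10.0) for r in ratios]


@dataclass
class GridSearchResult:
    grid: List[Tuple[float, float]]
    fold_scores: np.ndarray  # (n_configs, k)
    best_config: cslr.CSLRConfig
    cv_metric: str

    @property
    def mean_scores(self) -> np.ndarray:
        return self.fold_scores.mean(axis=1)


def _score_fold(model, X_val, y_val, cv_metric: str) -> float:
    if cv_metric == "f1":
        pred = cslr.classify(model, X_val)
        return f1_metric(y_val, pred)
    if cv_metric == "roc_auc":
        score = cslr.predict_proba(model, X_val)
        try:
            return rank_auc(y_val, score)
        except ValidationError:
            return float("nan")
    raise ValidationError(f"unknown cv_metric {cv_metric!r}")


def grid_search_cv(
    train_table: pd.DataFrame,
    feature_cols: Sequence[str],
    grid: Optional[List[Tuple[float, float]]] = None,
    k: int = 5,
    cv_metric: str = "f1",
    seed: int = 0,
    base_config: Optional[cslr.CSLRConfig] = None,
    n_repeats: int = 5,
) -> GridSearchResult:
    """Repeated stratified k-fold grid search over (l2_lambda, w_outlier).

    With only a handful of outliers per fold a single k-fold split gives a
    very noisy model-selection signal, so the k folds are redrawn
    ``n_repeats`` times and scores averaged over all k * n_repeats folds.
    The best configuration maximizes the mean fold score; ties are broken
    toward the more conservative model (larger l2_lambda, then larger
    relative normal-class weight, i.e. smaller w_outlier).
    """
    y = (train_table["label"].to_numpy() == "outlier").astype(int)
    n_out = int(y.sum())
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n_out < k:
        raise ValidationError(
            f"only {n_out} outliers for {k} folds; reduce k so every fold "
            "contains at least one outlier"
        )
    if grid is None:
        grid = default_grid(len(y) - n_out, n_out)
    base = base_config or cslr.CSLRConfig()
    X = train_table[list(feature_cols)]
    folds = []
    for r in range(max(1, n_repeats)):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        folds.extend(skf.split(X, y))
    scores = np.zeros((len(grid), len(folds)))
    for g, (lam, w_out) in enumerate(grid):
        cfg = base.replace(l2_lambda=lam, class_weights=(1.0, w_out))
        for j, (tr, va) in enumerate(folds):
            m = cslr.fit(X.iloc[tr], y[tr], cfg)
            scores[g, j] = _score_fold(m, X.iloc[va], y[va], cv_metric)
    means = np.nanmean(scores, axis=1)
    # winner's-curse guard (one-SE rule): among configurations within one
    # standard error of the best mean fold score, prefer the most
    # conservative model (largest l2_lambda, then smallest w_outlier)
    top = int(np.nanargmax(means))
    se = float(np.nanstd(scores[top]) / np.sqrt(scores.shape[1]))
    candidates = [g for g in range(len(grid)) if means[g] >= means[top] - se]
    # a configuration whose every fold score is beaten by some other
    # candidate is never selected
    def dominated(g):
        return any(
            np.all(scores[h] >= scores[g]) and np.any(scores[h] > scores[g])
            for h in candidates
            if h != g
        )

    candidates = [g for g in candidates if not dominated(g)] or candidates
    best = max(candidates, key=lambda g: (grid[g][0], -grid[g][1], means[g]))
    lam, w_out = grid[best]
    return GridSearchResult(
        grid=list(grid),
        fold_scores=scores,
        best_config=base.replace(l2_lambda=lam, class_weights=(1.0, w_out)),
        cv_metric=cv_metric,
    )


def learning_curves(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    config: cslr.CSLRConfig,
    train_sizes: Sequence[float] = (0.4, 0.6, 0.8, 1.0),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/validation F1 and ROC-AUC as a function of training-set size.

    For each size fraction: stratified subsample, stratified k-fold CV, and
    mean +/- SD of both metrics on the training folds and the held-out
    folds.  Infeasible sizes (fewer outliers than folds) are skipped.
    """
    y_all = (table["label"].to_numpy() == "outlier").astype(int)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in train_sizes:
        n_sub = max(2 * k, int(round(frac * len(table))))
        spec = SplitSpec(
            test_fraction=min(0.999, max(1e-9, 1.0 - n_sub / len(table))),
            seed=int(rng.integers(2**31)),
        )
        if n_sub >= len(table):
            sub = table
        else:
            sub, _ = stratified_split(table, spec)
        y = (sub["label"].to_numpy() == "outlier").astype(int)
        if y.sum() < k:
            continue
        X = sub[list(feature_cols)]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        rec: Dict[str, List[float]] = {
            "train_f1": [], "val_f1": [], "train_auc": [], "val_auc": []
        }
        for tr, va in skf.split(X, y):
            m = cslr.fit(X.iloc[tr], y[tr], config)
            rec["train_f1"].append(f1_metric(y[tr], cslr.classify(m, X.iloc[tr])))
            rec["val_f1"].append(f1_metric(y[va], cslr.classify(m, X.iloc[va])))
            rec["train_auc"].append(rank_auc(y[tr], cslr.predict_proba(m, X.iloc[tr])))
            try:
                rec["val_auc"].append(
                    rank_auc(y[va], cslr.predict_proba(m, X.iloc[va]))
                )
            except ValidationError:
                pass
        row = {"size": len(sub), "fraction": frac}
        for key, vals in rec.items():
            row[f"{key}_mean"] = float(np.mean(vals))
            row[f"{key}_sd"] = float(np.std(vals))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _exact_signed_rank_sf(w_plus: float, n: int) -> Tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact null for ranks 1..n.

    Dynamic programming over achievable rank sums; identical to enumerating
    all 2^n sign assignments.
    """
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    total = 2.0**n
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum() / total
    p_ge = counts[w:].sum() / total
    return p_le, p_ge


def compare_models(
    paired_scores_a: Sequence[float], paired_scores_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired model scores.

    Zero differences are dropped.  For n <= 25 untied absolute differences
    the exact null distribution is used; otherwise a normal approximation
    with tie correction.  Returns (W+, two-sided p).
    """
    a = np.asarray(paired_scores_a, dtype=float)
    b = np.asarray(paired_scores_b, dtype=float)
    if len(a) != len(b):
        raise ValidationError("paired score vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        p_le, p_ge = _exact_signed_rank_sf(w_plus, n)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, p
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0
    from scipy.stats import norm

    z = (w_plus - mean) / math.sqrt(var)
    return w_plus, float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    split: SplitSpec = field(default_factory=SplitSpec)
    grid: Optional[List[Tuple[float, float]]] = None
    k: int = 5
    cv_metric: str = "f1"
    bootstrap_reps: int = 1000
    learning_curve_sizes: Tuple[float, ...] = (0.4, 0.6, 0.8, 1.0)
    run_learning_curves: bool = True
    wilcoxon_repeats: int = 5  # repeated-CV repetitions for paired scores
    seed: int = 0


def _eval_report(model, X, y_true, reps: int, seed: int) -> Dict[str, object]:
    pred = cslr.classify(model, X)
    score = cslr.predict_proba(model, X)
    rep = metrics(y_true, pred, y_score=score)
    rep["ci_95"] = {
        "f1": bootstrap_ci(y_true, pred, f1_metric, reps=reps, seed=seed),
        "precision": bootstrap_ci(
            y_true, pred, precision_metric, reps=reps, seed=seed + 1
        ),
        "recall": bootstrap_ci(y_true, pred, recall_metric, reps=reps, seed=seed + 2),
        "roc_auc": bootstrap_ci(y_true, score, rank_auc, reps=reps, seed=seed + 3),
    }
    return rep


def _paired_cv_scores(
    table: pd.DataFrame,
    feature_sets: Dict[str, List[str]],
    configs: Dict[str, cslr.CSLRConfig],
    k: int,
    repeats: int,
    seed: int,
) -> Dict[str, List[float]]:
    """Per-fold F1 from repeated stratified CV, folds shared across models."""
    y = (table["label"].to_numpy() == "outlier").astype(int)
    out: Dict[str, List[float]] = {tag: [] for tag in feature_sets}
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for tr, va in skf.split(table, y):
            for tag, cols in feature_sets.items():
                m = cslr.fit(table[cols].iloc[tr], y[tr], configs[tag])
                out[tag].append(
                    f1_metric(y[va], cslr.classify(m, table[cols].iloc[va]))
                )
    return out


def run_experiment(
    feature_table: pd.DataFrame, config: Optional[ExperimentConfig] = None
) -> Dict[str, object]:
    """Run the full protocol on a feature table; both feature sets.

    Stratified 60/40 split; per feature set: stratified k-fold grid search
    on the training rows, refit on the full training set, evaluation on the
    held-out test set with bootstrap CIs, learning curves; finally a
    Wilcoxon signed-rank comparison of paired repeated-CV F1 scores.
    Deterministic given ``config.seed``.
    """
    config = config or ExperimentConfig()
    spec = dataclasses.replace(config.split, seed=config.split.seed or config.seed)
    train, test = stratified_split(feature_table, spec)
    y_train = (train["label"].to_numpy() == "outlier").astype(int)
    y_test = (test["label"].to_numpy() == "outlier").astype(int)

    report: Dict[str, object] = {
        "config": {
            "seed": config.seed,
            "k": config.k,
            "cv_metric": config.cv_metric,
            "test_fraction": spec.test_fraction,
        },
        "split": {
            "n_train": int(len(train)),
            "n_test": int(len(test)),
            "train_outliers": int(y_train.sum()),
            "test_outliers": int(y_test.sum()),
            "train_ids": train["measurement_id"].tolist(),
            "test_ids": test["measurement_id"].tolist(),
        },
        "models": {},
    }
    best_configs: Dict[str, cslr.CSLRConfig] = {}
    fitted: Dict[str, cslr.FittedCSLR] = {}
    for tag, cols in FEATURE_SETS.items():
        gs = grid_search_cv(
            train,
            cols,
            grid=config.grid,
            k=config.k,
            cv_metric=config.cv_metric,
            seed=config.seed,
        )
        best_configs[tag] = gs.best_config
        m = cslr.fit(train[cols], y_train, gs.best_config)
        fitted[tag] = m
        entry: Dict[str, object] = {
            "best_config": {
                "l2_lambda": gs.best_config.l2_lambda,
                "class_weights": list(gs.best_config.class_weights),
            },
            "cv_mean_score": float(np.nanmean(gs.fold_scores, axis=1).max()),
            "train": _eval_report(
                m, train[cols], y_train, config.bootstrap_reps, config.seed
            ),
            "test": _eval_report(
                m, test[cols], y_test, config.bootstrap_reps, config.seed
            ),
        }
        if config.run_learning_curves:
            entry["learning_curves"] = learning_curves(
                train,
                cols,
                gs.best_config,
                train_sizes=config.learning_curve_sizes,
                k=config.k,
                seed=config.seed,
            ).to_dict(orient="records")
        report["models"][tag] = entry

    if config.wilcoxon_repeats > 0:
        paired = _paired_cv_scores(
            train,
            FEATURE_SETS,
            best_configs,
            k=config.k,
            repeats=config.wilcoxon_repeats,
            seed=config.seed,
        )
        w, p = compare_models(paired["engineered"], paired["basic"])
        report["wilcoxon"] = {
            "W": w,
            "p_value": p,
            "n_pairs": len(paired["basic"]),
            "mean_f1_basic": float(np.mean(paired["basic"])),
            "mean_f1_engineered": float(np.mean(paired["engineered"])),
        }
    report["_fitted_models"] = fitted
    return report
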