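"""Gradient-boosted classification of trial outcome with wrapper feature
selection under nested cross-validation.

The classifier is an XGBoost ensemble of 30 trees of maximum depth 4
(subject-/session-specific models).  Feature subsets are chosen by greedy
forward ("wrapper") selection: at each step the candidate feature whose
addition maximizes the inner 5-fold cross-validated F1 is added, until a
feature budget is reached or the score stops improving.  The outer 5-fold
stratified loop sees the selection only through the training folds, so
reported metrics are honest estimates of generalization.  The positive
class is the incorrect trial throughout.

Missing feature values (degenerate Hjorth ratios etc.) are imputed with
training-fold medians; test folds never contribute to any statistic used
in training.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .biomarkers import FeatureConfig, FeatureTable, extract_features
from .core import SessionRecording, TrialEvent, extract_epochs

POSITIVE_CLASS = "incorrect"


@dataclass(frozen=True)
class ModelConfig:
    """Ensemble hyperparameters; only tree count and depth follow the
    original protocol, the rest are fixed library defaults recorded here."""

    n_trees: int = 30
    max_depth: int = 4
    learning_rate: float = 0.3
    reg_lambda: float = 1.0
    #: None lets the library estimate the intercept from the training
    #: class prior (its default); a float fixes it (0.5 = neutral)
    base_score: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")

    def params(self) -> dict:
        out = {
            "objective": "binary:logistic",
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "lambda": self.reg_lambda,
            "tree_method": "hist",
            "nthread": 1,
            "seed": self.seed,
            "verbosity": 0,
        }
        if self.base_score is not None:
            out["base_score"] = self.base_score
        return out


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ModelConfig,
) -> np.ndarray:
    """Train the ensemble and return 0/1 predictions on the test block."""
    dtrain = xgb.DMatrix(np.ascontiguousarray(X_train), label=y_train)
    booster = xgb.train(config.params(), dtrain, num_boost_round=config.n_trees)
    prob = booster.predict(xgb.DMatrix(np.ascontiguousarray(X_test)))
    return (prob > 0.5).astype(int)


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    return tp, fp, tn, fn


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Six metrics from confusion counts; degenerate denominators yield NaN
    (and F1 is 0 when precision + sensitivity = 0)."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn < 1:
        raise ValueError("counts must be non-negative with at least one trial")
    nan = float("nan")
    precision = tp / (tp + fp) if tp + fp > 0 else nan
    sensitivity = tp / (tp + fn) if tp + fn > 0 else nan
    specificity = tn / (tn + fp) if tn + fp > 0 else nan
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    if math.isnan(precision) or math.isnan(sensitivity):
        f1 = nan
    elif precision + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    balanced = (
        (sensitivity + specificity) / 2
        if not (math.isnan(sensitivity) or math.isnan(specificity))
        else nan
    )
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "f1": f1,
        "balanced_accuracy": balanced,
    }


def all_positive_baseline(n_incorrect: int, n_correct: int) -> float:
    """F1 of the trivial detector labelling every trial incorrect:
    sensitivity 1, precision P/(P+N), F1 = 2P/(2P+N)."""
    if n_incorrect < 1:
        raise ValueError("need at least one incorrect trial")
    return 2 * n_incorrect / (2 * n_incorrect + n_correct)


# ---------------------------------------------------------------------------
# imputation (training-fold medians only)


def _train_medians(X: np.ndarray) -> np.ndarray:
    with np.errstate(all="ignore"):
        med = np.nanmedian(X, axis=0)
    return np.where(np.isfinite(med), med, 0.0)


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    out = X.copy()
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = np.broadcast_to(medians, out.shape)[bad]
    return out


def point_biserial_r2(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each column with the binary label
    (the univariate feature-ranking statistic)."""
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    return r**2


# ---------------------------------------------------------------------------
# wrapper forward selection


@dataclass
class SelectionResult:
    #: column names in the order they were picked (trimmed at the best score)
    selected: list[str]
    #: inner-CV F1 after each greedy addition (full, untrimmed curve)
    curve: list[float]
    #: every greedy pick, including trailing non-improving ones
    picks: list[str]


def _inner_cv_f1(
    X: np.ndarray,
    y: np.ndarray,
    cols: list[int],
    config: ModelConfig,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    tp = fp = tn = fn = 0
    sub = X[:, cols]
    for tr, te in folds:
        pred = fit_predict(sub[tr], y[tr], sub[te], config)
        a, b, c, d = confusion_counts(y[te], pred)
        tp, fp, tn, fn = tp + a, fp + b, tn + c, fn + d
    m = compute_metrics(tp, fp, tn, fn)
    f1 = m["f1"]
    return 0.0 if math.isnan(f1) else f1


def wrapper_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    config: ModelConfig | None = None,
    k_max: int = 15,
    inner_folds: int = 5,
    tol: float = 1e-3,
    patience: int = 2,
    screen_top_m: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Greedy forward selection scored by inner stratified 5-fold CV F1.

    Each step adds the candidate maximizing the pooled inner-CV F1 of the
    ensemble on the current set (ties broken by lower column index), and
    stops at ``k_max`` features or when the score has failed to improve by
    ``tol`` for ``patience`` consecutive steps.  ``screen_top_m`` limits
    the candidate pool to the m columns with the highest point-biserial R²
    on this (training) data — a desk-scale shortcut for very wide tables;
    None scans every column.  Deterministic for a fixed seed.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    config = config or ModelConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    medians = _train_medians(X)
    X = _impute(X, medians)

    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]
    for _, te in folds:
        if len(np.unique(y[te])) < 2:
            raise ValueError("both classes must be present in every inner fold")

    candidates = list(range(X.shape[1]))
    if screen_top_m is not None and screen_top_m < len(candidates):
        r2 = point_biserial_r2(X, y)
        ranked = np.argsort(-r2, kind="stable")[:screen_top_m]
        candidates = sorted(int(i) for i in ranked)

    chosen: list[int] = []
    curve: list[float] = []
    best_score = -np.inf
    stale = 0
    while len(chosen) < min(k_max, len(candidates)):
        step_best, step_col = -np.inf, None
        for col in candidates:
            if col in chosen:
                continue
            score = _inner_cv_f1(X, y, chosen + [col], config, folds)
            if score > step_best:  # strict: first (lowest-index) max wins
                step_best, step_col = score, col
        chosen.append(step_col)
        curve.append(step_best)
        if step_best >= best_score + tol:
            best_score = step_best
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    k_best = int(np.argmax(curve)) + 1
    names = [feature_names[i] for i in chosen]
    return SelectionResult(selected=names[:k_best], curve=curve, picks=names)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class EvalReport:
    """Nested-CV evaluation record for one feature-set condition."""

    condition: str
    pooled: dict[str, float]
    pooled_counts: dict[str, int]
    per_fold: list[dict]
    fold_mean: dict[str, float]
    baseline_f1: float
    selected_per_fold: list[list[str]]
    curves: list[list[float]]
    n_trials: int
    n_incorrect: int
    period: str | None = None
    window_s: float | None = None
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.pooled
        if not math.isnan(m.get("balanced_accuracy", float("nan"))):
            assert math.isclose(
                m["balanced_accuracy"],
                (m["sensitivity"] + m["specificity"]) / 2,
                rel_tol=0,
                abs_tol=1e-12,
            )

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, float)):
                f = float(o)
                return None if math.isnan(f) else f
            if isinstance(o, (np.integer,)):
                return int(o)
            return o

        return json.dumps(clean(self.__dict__), indent=1, sort_keys=True)


def _index_hash(idx: np.ndarray) -> str:
    return hashlib.sha1(np.sort(np.asarray(idx)).astype(np.int64).tobytes()).hexdigest()[:12]


def nested_cv_evaluate(
    table: FeatureTable,
    config: ModelConfig | None = None,
    condition: str = "combined",
    k_max: int = 15,
    n_outer: int = 5,
    inner_folds: int = 5,
    screen_top_m: int | None = None,
    seed: int = 0,
    columns: list[str] | None = None,
) -> EvalReport:
    """Outer stratified 5-fold evaluation with per-fold wrapper selection.

    The condition restricts candidate columns: ``spectral`` (band powers),
    ``HOST`` (all higher-order spectrotemporal and connectivity families)
    or ``combined``; ``columns`` overrides the condition with an explicit
    candidate list.  Per outer fold, selection and imputation statistics
    come from the training portion only; the refitted model is scored on
    the held-out fold.  Pooled metrics sum confusion counts over folds;
    per-fold means are reported alongside.
    """
    config = config or ModelConfig()
    cols = columns if columns is not None else table.columns_for_condition(condition)
    if len(cols) < 2:
        raise ValueError("need at least 2 candidate columns")
    X = table.values[cols].to_numpy(dtype=np.float64)
    y = table.labels
    n_minority = int(min(y.sum(), len(y) - y.sum()))
    if len(y) < 25 or n_minority < n_outer:
        raise ValueError(
            f"need >= 25 trials with >= {n_outer} of each class for stratified "
            f"nested CV; have {len(y)} trials, minority class {n_minority} — "
            "collect more data"
        )
    skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    per_fold, selected_per_fold, curves, audit_folds = [], [], [], []
    for fold_i, (tr, te) in enumerate(skf.split(X, y)):
        sel = wrapper_select(
            X[tr],
            y[tr],
            cols,
            config=config,
            k_max=k_max,
            inner_folds=inner_folds,
            screen_top_m=screen_top_m,
            seed=seed + fold_i,
        )
        keep = [cols.index(c) for c in sel.selected]
        medians = _train_medians(X[tr][:, keep])
        Xtr = _impute(X[tr][:, keep], medians)
        Xte = _impute(X[te][:, keep], medians)
        pred = fit_predict(Xtr, y[tr], Xte, config)
        a, b, c, d = confusion_counts(y[te], pred)
        tp, fp, tn, fn = tp + a, fp + b, tn + c, fn + d
        per_fold.append(compute_metrics(a, b, c, d))
        selected_per_fold.append(sel.selected)
        curves.append(sel.curve)
        audit_folds.append(
            {"train_hash": _index_hash(tr), "test_hash": _index_hash(te),
             "n_train": int(len(tr)), "n_test": int(len(te))}
        )
    pooled = compute_metrics(tp, fp, tn, fn)
    fold_mean = {
        k: float(np.nanmean([m[k] for m in per_fold])) for k in per_fold[0]
    }
    return EvalReport(
        condition=condition if columns is None else "custom",
        pooled=pooled,
        pooled_counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        per_fold=per_fold,
        fold_mean=fold_mean,
        baseline_f1=all_positive_baseline(int(y.sum()), int(len(y) - y.sum())),
        selected_per_fold=selected_per_fold,
        curves=curves,
        n_trials=int(len(y)),
        n_incorrect=int(y.sum()),
        audit={"folds": audit_folds, "seed": seed},
    )


def single_channel_evaluation(
    table: FeatureTable,
    config: ModelConfig | None = None,
    k_max: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Pooled nested-CV F1 per electrode, using only that electrode's
    single-channel features (connectivity and global columns excluded).
    Channels whose features carry no usable signal land near baseline."""
    channels = sorted({info.channels[0] for info in table.registry.values()
                       if len(info.channels) == 1})
    out = {}
    for ch in channels:
        cols = table.columns_for_channel(ch)
        rep = nested_cv_evaluate(
            table, config=config, columns=cols, k_max=k_max, seed=seed
        )
        out[ch] = rep.pooled["f1"]
    return out


def period_comparison(
    sessions: list[tuple[SessionRecording, list[TrialEvent]]],
    periods: Sequence[str] = ("pre_target", "target", "delay"),
    windows: Sequence[float] = (1.0,),
    model_config: ModelConfig | None = None,
    feature_config: FeatureConfig | None = None,
    k_max: int = 5,
    screen_top_m: int | None = 30,
    seed: int = 0,
):
    """Run the full epoch → features → nested-CV pipeline per period and
    window; returns a DataFrame of pooled F1 next to the all-positive
    baseline (confusion counts pooled across sessions)."""
    import pandas as pd

    rows = []
    for period in periods:
        for window_s in windows:
            tp = fp = tn = fn = 0
            n_pos = n_neg = 0
            for si, (session, events) in enumerate(sessions):
                epochs = extract_epochs(session, events, period, window_s)
                table = extract_features(epochs, feature_config)
                rep = nested_cv_evaluate(
                    table,
                    config=model_config,
                    k_max=k_max,
                    screen_top_m=screen_top_m,
                    seed=seed + si,
                )
                n_pos += rep.n_incorrect
                n_neg += rep.n_trials - rep.n_incorrect
                c = rep.pooled_counts
                tp += c["tp"]
                fp += c["fp"]
                tn += c["tn"]
                fn += c["fn"]
            m = compute_metrics(tp, fp, tn, fn)
            rows.append(
                {
                    "period": period,
                    "window_s": window_s,
                    "f1": m["f1"],
                    "accuracy": m["accuracy"],
                    "balanced_accuracy": m["balanced_accuracy"],
                    "baseline_f1": all_positive_baseline(n_pos, n_neg),
                }
            )
    return pd.DataFrame(rows)
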