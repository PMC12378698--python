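"""Feature selection and leave-one-out cross-validated ridge regression.

The modeling pipeline mirrors common practice for small-cohort individual-
differences prediction: rank the navigation features (by absolute Pearson
correlation with the target, or by gradient-boosting importance), grow the
model by adding features in rank order, optionally prune it by backward
elimination, and score every candidate subset by leave-one-out
cross-validated (LOOCV) mean squared error of an L2-regularized linear
model on standardized features.  The winning subset is refit on all data
and its in-sample prediction range is stored so new predictions can be
reported on a relative 0–1 (or 0–100 display) scale.

Leakage control: inside LOOCV the scaler is fit on the n−1 training rows of
each fold only; the held-out row never touches its fold's standardization.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, DataError
from .multiplex import MultiplexNetwork, aggregate_graph, largest_viable_cluster, layer_lcc
from .walks import FEATURE_NAMES, feature_table

logger = logging.getLogger(__name__)

__all__ = [
    "RankedFeatures",
    "EvaluationReport",
    "TrainedModel",
    "impute_median",
    "correlate_features",
    "rank_features_cfs",
    "rank_features_boosting",
    "loocv_evaluate",
    "incremental_forward_selection",
    "backward_elimination",
    "fit_final_model",
    "predict_scores",
    "select_and_train",
    "compare_single_layer_models",
]

MODEL_SCHEMA = "cognav-model-1"

#: Boosting ranker hyperparameters, fixed for reproducibility.
BOOSTING_PARAMS = dict(n_estimators=500, max_depth=6, learning_rate=0.05,
                       loss="squared_error")


@dataclass(frozen=True)
class RankedFeatures:
    """Feature importance ranking: most important first, ties by name."""

    method: str                      # "correlation" or "boosting"
    order: tuple                     # feature names, descending importance
    scores: Mapping[str, float]      # importance per feature


@dataclass
class EvaluationReport:
    """Held-out performance of one feature subset under LOOCV.

    ``r_squared`` is the squared Pearson correlation between held-out
    predictions and actual scores.
    """

    mse: float
    pearson_r: float
    p_value: float
    r_squared: float
    per_fold_predictions: pd.Series

    def to_dict(self) -> dict:
        return {"mse": self.mse, "pearson_r": self.pearson_r,
                "p_value": self.p_value, "r_squared": self.r_squared}


@dataclass
class TrainedModel:
    """A deployable model: subset, scaler, ridge coefficients, prediction
    range for relative 0–1 normalization, and training medians for
    imputation of missing features at predict time."""

    target: str
    features: tuple
    scaler_mean: tuple
    scaler_scale: tuple
    coefficients: tuple
    intercept: float
    l2_strength: float
    train_pred_min: float
    train_pred_max: float
    feature_medians: Mapping[str, float] = field(default_factory=dict)
    selection_method: Optional[str] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "schema": MODEL_SCHEMA,
            "target": self.target,
            "features": list(self.features),
            "scaler_mean": list(self.scaler_mean),
            "scaler_scale": list(self.scaler_scale),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "l2_strength": self.l2_strength,
            "train_pred_min": self.train_pred_min,
            "train_pred_max": self.train_pred_max,
            "feature_medians": dict(self.feature_medians),
            "selection_method": self.selection_method,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TrainedModel":
        if payload.get("schema") != MODEL_SCHEMA:
            raise DataError(
                f"unsupported model schema {payload.get('schema')!r}; "
                f"expected {MODEL_SCHEMA!r}")
        return cls(
            target=payload["target"],
            features=tuple(payload["features"]),
            scaler_mean=tuple(payload["scaler_mean"]),
            scaler_scale=tuple(payload["scaler_scale"]),
            coefficients=tuple(payload["coefficients"]),
            intercept=payload["intercept"],
            l2_strength=payload["l2_strength"],
            train_pred_min=payload["train_pred_min"],
            train_pred_max=payload["train_pred_max"],
            feature_medians=dict(payload.get("feature_medians", {})),
            selection_method=payload.get("selection_method"),
            seed=payload.get("seed"),
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text("utf-8")))


def impute_median(table: pd.DataFrame) -> pd.DataFrame:
    """Replace NaNs with the per-column median (cohort-median imputation
    for degenerate-walk participants).  All-NaN columns become 0."""
    medians = table.median()
    return table.fillna(medians).fillna(0.0)


def _aligned(table: pd.DataFrame, target: pd.Series):
    target = target.reindex(table.index)
    if target.isna().any():
        missing = list(target[target.isna()].index)
        raise DataError(f"target missing for participants: {missing[:5]}")
    return table, target


def correlate_features(table: pd.DataFrame, target: pd.Series):
    """Pearson r and two-sided p of each feature vs the target.

    Missing feature values are pairwise-dropped; constant features yield
    NaN with a warning.  Returns a DataFrame indexed by feature with
    columns ``r`` and ``p``.
    """
    table, target = _aligned(table, target)
    if len(table) < 3:
        raise ConfigurationError("need at least 3 rows for correlations")
    rows = {}
    for name in table.columns:
        col = table[name]
        ok = col.notna() & target.notna()
        x, y = col[ok].to_numpy(float), target[ok].to_numpy(float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("feature %r: correlation undefined (constant or "
                           "too few values)", name)
            rows[name] = (math.nan, math.nan)
            continue
        r, p = _sstats.pearsonr(x, y)
        rows[name] = (float(r), float(p))
    return pd.DataFrame(rows, index=["r", "p"]).T


def rank_features_cfs(table: pd.DataFrame, target: pd.Series) -> RankedFeatures:
    """Correlation-based ranking: descending |Pearson r| with the target."""
    corr = correlate_features(table, target)
    scores = corr["r"].abs().fillna(-math.inf)
    order = tuple(sorted(table.columns, key=lambda f: (-scores[f], f)))
    return RankedFeatures(method="correlation", order=order,
                          scores={f: float(scores[f]) for f in order})


def rank_features_boosting(table: pd.DataFrame, target: pd.Series,
                           seed: int = 0) -> RankedFeatures:
    """Gradient-boosting importance ranking (squared-error loss).

    Trains a fixed-seed gradient-boosted tree ensemble and ranks features by
    impurity-based importance, descending.  A constant target makes every
    importance zero; the ranking then degenerates to name order and is
    flagged in the log.
    """
    table, target = _aligned(table, target)
    if len(table) < 10:
        raise ConfigurationError("boosting ranking needs at least 10 rows")
    x = impute_median(table).to_numpy(float)
    y = target.to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in features or target")
    model = GradientBoostingRegressor(random_state=seed, **BOOSTING_PARAMS)
    model.fit(x, y)
    imp = dict(zip(table.columns, model.feature_importances_))
    if all(v == 0 for v in imp.values()):
        logger.warning("boosting ranking degenerate: all importances zero")
    order = tuple(sorted(table.columns, key=lambda f: (-imp[f], f)))
    return RankedFeatures(method="boosting", order=order,
                          scores={f: float(imp[f]) for f in order})


def _fit_linear(x: np.ndarray, y: np.ndarray, l2: float):
    """Fit (standardized) ridge / plain least squares; returns the sklearn
    estimator.  ``l2 == 0`` falls back to ordinary least squares."""
    if l2 > 0:
        est = Ridge(alpha=l2)
    else:
        est = LinearRegression()
    est.fit(x, y)
    return est


def loocv_evaluate(table: pd.DataFrame, target: pd.Series,
                   subset: Sequence[str], l2_strength: float = 1.0
                   ) -> EvaluationReport:
    """Leave-one-out evaluation of one feature subset.

    Per fold, the scaler is fit on the n−1 training rows only and both
    partitions are standardized with it; an L2-regularized linear model fit
    on the training rows predicts the held-out row.  Features that are
    constant within a training fold are dropped for that fold (with a
    warning).  MSE, Pearson r, its p-value and r² are aggregated over the n
    held-out predictions.
    """
    subset = list(subset)
    if not subset:
        raise ConfigurationError("empty feature subset")
    unknown = [f for f in subset if f not in table.columns]
    if unknown:
        raise ConfigurationError(f"unknown features: {unknown}")
    table, target = _aligned(table, target)
    n = len(table)
    if n < 5:
        raise ConfigurationError(f"LOOCV needs at least 5 rows, got {n}")
    x_all = impute_median(table[subset]).to_numpy(float)
    y_all = target.to_numpy(float)
    preds = np.empty(n)
    mask = np.ones(n, bool)
    dropped_any: set = set()
    for i in range(n):
        mask[:] = True
        mask[i] = False
        x_train, y_train = x_all[mask], y_all[mask]
        keep = x_train.std(axis=0) > 0
        if not keep.all():
            dropped_any.update(f for f, k in zip(subset, keep) if not k)
        if not keep.any():
            preds[i] = y_train.mean()
            continue
        scaler = StandardScaler().fit(x_train[:, keep])
        est = _fit_linear(scaler.transform(x_train[:, keep]), y_train,
                          l2_strength)
        preds[i] = est.predict(
            scaler.transform(x_all[i:i + 1, keep]))[0]
    if dropped_any:
        logger.warning("zero-variance features dropped in some folds: %s",
                       sorted(dropped_any))
    mse = float(np.mean((preds - y_all) ** 2))
    if np.ptp(preds) == 0 or np.ptp(y_all) == 0:
        r, p = math.nan, math.nan
    else:
        r, p = (float(v) for v in _sstats.pearsonr(preds, y_all))
    return EvaluationReport(
        mse=mse, pearson_r=r, p_value=p,
        r_squared=(r * r if not math.isnan(r) else math.nan),
        per_fold_predictions=pd.Series(preds, index=table.index,
                                       name="prediction"),
    )


def incremental_forward_selection(ranked: RankedFeatures, table: pd.DataFrame,
                                  target: pd.Series, l2_strength: float = 1.0):
    """Evaluate every prefix of the ranking; return the prefix with the
    lowest LOOCV MSE (ties go to the smaller prefix)."""
    if not ranked.order:
        raise ConfigurationError("empty ranking")
    best_subset, best_report = None, None
    for k in range(1, len(ranked.order) + 1):
        subset = list(ranked.order[:k])
        report = loocv_evaluate(table, target, subset, l2_strength)
        logger.info("forward selection: top-%d MSE=%.6g", k, report.mse)
        if best_report is None or report.mse < best_report.mse:
            best_subset, best_report = subset, report
    return best_subset, best_report


def backward_elimination(table: pd.DataFrame, target: pd.Series,
                         start_subset: Sequence[str],
                         l2_strength: float = 1.0,
                         return_trajectory: bool = False):
    """Iteratively drop the feature whose removal increases LOOCV MSE the
    least (i.e., yields the lowest MSE); stop when every single removal
    would raise the MSE above the current set's, or one feature remains.
    Returns the subset with the lowest MSE seen anywhere on the trajectory
    (and, with ``return_trajectory``, the full ``[(subset, report), ...]``
    elimination record).
    """
    current = list(start_subset)
    if len(current) < 2:
        raise ConfigurationError("backward elimination needs >= 2 features")
    current_report = loocv_evaluate(table, target, current, l2_strength)
    trajectory = [(tuple(current), current_report)]
    # MSE increases below numerical noise (relative to the target's scale)
    # count as "no increase", so redundant copies are still eliminated.
    tol = 1e-9 * float(np.var(target.to_numpy(float)))
    while len(current) > 1:
        candidates = []
        for f in sorted(current):
            reduced = [g for g in current if g != f]
            report = loocv_evaluate(table, target, reduced, l2_strength)
            candidates.append((report.mse, f, reduced, report))
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_mse, removed, reduced, report = candidates[0]
        if best_mse > current_report.mse + tol:
            break
        logger.info("backward elimination: removed %r, MSE %.6g -> %.6g",
                    removed, current_report.mse, best_mse)
        current, current_report = reduced, report
        trajectory.append((tuple(current), report))
    min_mse = min(rep.mse for _, rep in trajectory)
    best_subset, best_report = min(
        (t for t in trajectory if t[1].mse <= min_mse + tol),
        key=lambda t: (len(t[0]), t[1].mse))
    if return_trajectory:
        return list(best_subset), best_report, trajectory
    return list(best_subset), best_report


def fit_final_model(table: pd.DataFrame, target: pd.Series,
                    subset: Sequence[str], l2_strength: float = 1.0,
                    selection_method: Optional[str] = None,
                    seed: Optional[int] = None) -> TrainedModel:
    """Refit the selected subset on all rows and package a deployable model.

    The scaler is fit on the full table (deployment convention); the
    in-sample prediction range is stored for relative 0–1 normalization of
    future predictions.  Zero-variance features are rejected, and a singular
    unregularized design raises an error suggesting a nonzero L2 strength.
    """
    subset = list(subset)
    if not subset:
        raise ConfigurationError("empty feature subset")
    table, target = _aligned(table, target)
    medians = table.median().to_dict()
    x = impute_median(table[subset]).to_numpy(float)
    y = target.to_numpy(float)
    sds = x.std(axis=0)
    if (sds == 0).any():
        bad = [f for f, s in zip(subset, sds) if s == 0]
        raise DataError(f"zero-variance features at fit time: {bad}")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    if l2_strength == 0 and np.linalg.matrix_rank(xs) < xs.shape[1]:
        raise DataError("singular design with l2_strength=0; use a nonzero "
                        "L2 strength")
    est = _fit_linear(xs, y, l2_strength)
    preds = est.predict(xs)
    return TrainedModel(
        target=str(target.name or "target"),
        features=tuple(subset),
        scaler_mean=tuple(float(m) for m in scaler.mean_),
        scaler_scale=tuple(float(s) for s in scaler.scale_),
        coefficients=tuple(float(c) for c in est.coef_),
        intercept=float(est.intercept_),
        l2_strength=float(l2_strength),
        train_pred_min=float(preds.min()),
        train_pred_max=float(preds.max()),
        feature_medians={k: (float(v) if np.isfinite(v) else 0.0)
                         for k, v in medians.items()},
        selection_method=selection_method,
        seed=seed,
    )


def predict_scores(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score new participants with a trained model.

    Returns a DataFrame with ``raw`` (ridge prediction), ``unit`` (raw
    rescaled by the training prediction range and clipped to [0, 1]) and
    ``display`` (0–100).  100 means "as high as the highest prediction seen
    in training", a relative, not absolute, benchmark.
    """
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise DataError(f"feature table lacks model features: {missing}")
    cols = features[list(model.features)].copy()
    for f in model.features:
        cols[f] = cols[f].fillna(model.feature_medians.get(f, 0.0))
    x = cols.to_numpy(float)
    xs = (x - np.asarray(model.scaler_mean)) / np.asarray(model.scaler_scale)
    raw = xs @ np.asarray(model.coefficients) + model.intercept
    span = model.train_pred_max - model.train_pred_min
    if span == 0:
        logger.warning("degenerate training prediction range; unit scores "
                       "fixed at 0.5")
        unit = np.full_like(raw, 0.5)
    else:
        unit = np.clip((raw - model.train_pred_min) / span, 0.0, 1.0)
    return pd.DataFrame(
        {"raw": raw, "unit": unit, "display": 100.0 * unit},
        index=features.index)


def select_and_train(table: pd.DataFrame, target: pd.Series,
                     method: str = "auto", l2_strength: float = 1.0,
                     seed: int = 0, backward: bool = True):
    """Full selection + training for one target.

    ``method`` is ``"cfs"``, ``"boosting"`` or ``"auto"`` (run both, keep
    the one with lower LOOCV MSE).  Each route ranks features, runs
    incremental forward selection over ranking prefixes and (optionally)
    backward elimination from the forward winner, keeping whichever subset
    scored the lowest LOOCV MSE.  Returns ``(TrainedModel, EvaluationReport,
    method_used)``.
    """
    if method not in ("cfs", "boosting", "auto"):
        raise ConfigurationError(f"unknown selection method {method!r}")
    methods = ("cfs", "boosting") if method == "auto" else (method,)
    results = {}
    for m in methods:
        if m == "cfs":
            ranked = rank_features_cfs(table, target)
        else:
            ranked = rank_features_boosting(table, target, seed=seed)
        subset, report = incremental_forward_selection(
            ranked, table, target, l2_strength)
        if backward and len(subset) >= 2:
            b_subset, b_report = backward_elimination(
                table, target, subset, l2_strength)
            if b_report.mse < report.mse:
                subset, report = b_subset, b_report
        results[m] = (subset, report)
    method_used = min(results, key=lambda m: (results[m][1].mse, m))
    subset, report = results[method_used]
    model = fit_final_model(table, target, subset, l2_strength,
                            selection_method=method_used, seed=seed)
    logger.info("target %r: method=%s subset=%s MSE=%.6g r=%.4f",
                target.name, method_used, subset, report.mse,
                report.pearson_r)
    return model, report, method_used


def compare_single_layer_models(mpx: MultiplexNetwork, cohort,
                                target: pd.Series, subset: Sequence[str],
                                l2_strength: float = 1.0, category=None
                                ) -> dict:
    """Multiplex/LVC model vs single-layer/LCC null models.

    For each layer, features are recomputed with connectivity restricted to
    that layer alone and the layer's largest connected component standing in
    for the LVC; the feature subset selected for the multiplex model is held
    fixed so the comparison isolates the network substrate.  Returns
    ``{"multiplex": report, <layer name>: report, ...}`` — one entry per
    layer plus the multiplex itself.
    """
    lvc = largest_viable_cluster(mpx).members
    reports: dict = {}
    graph = aggregate_graph(mpx)
    table = feature_table(cohort, graph, core=lvc, category=category)
    reports["multiplex"] = loocv_evaluate(table, target, subset, l2_strength)
    for layer in mpx.layers:
        lcc = layer_lcc(layer)
        layer_table = feature_table(cohort, layer.graph, core=lcc,
                                    category=category)
        reports[layer.name] = loocv_evaluate(layer_table, target, subset,
                                             l2_strength)
    return reports
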