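"""Shoot-biomass estimation from canopy features, with interpretation.

Four regressors are trained per view set on the seven canopy variables:
RBF-kernel support vector regression (grid over C and gamma), random forest
(500 trees, grid over mtry 1-4), gradient-boosted trees (grid over learning
rate, depth, gamma, subsample, min child weight and column subsample), and
bidirectional stepwise linear regression under AIC. The data are split
80/20, standardized on the training subset only, tuned by 5-fold
cross-validation RMSE, and evaluated on the held-out subset with R^2 and
RMSE plus post-hoc subgroup metrics. Feature attributions are Shapley
values: exact for linear models, a seeded permutation-sampling estimator for
the kernel/tree models (telescoping sums keep additivity exact up to
floating point).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

logger = logging.getLogger("vinephen.biomass_regression")

ALGORITHMS = ("SVR", "RF", "XGB", "STEPWISE")


class InvalidSplitError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionSpec:
    """Algorithm choice plus the hyperparameter grids and protocol constants.

    Grid defaults: SVR C in {1, 5, 10, 50, 100} and gamma in
    {0.01, 0.05, 0.1, 0.5, 1}; RF 500 unpruned trees with mtry 1-4; XGB
    learning rate {0.01, 0.1, 0.3}, max depth {3, 6, 9}, gamma {0, 0.1, 0.2},
    subsample {0.6, 0.8, 1.0}, min child weight {1, 3, 5}, column subsample
    {0.6, 0.8, 1.0}. 5-fold CV, 80/20 split.
    """

    algorithm: str = "SVR"
    svr_C_grid: tuple = (1, 5, 10, 50, 100)
    svr_gamma_grid: tuple = (0.01, 0.05, 0.1, 0.5, 1)
    rf_trees: int = 500
    rf_mtry_grid: tuple = (1, 2, 3, 4)
    xgb_learning_rate: tuple = (0.01, 0.1, 0.3)
    xgb_max_depth: tuple = (3, 6, 9)
    xgb_gamma: tuple = (0.0, 0.1, 0.2)
    xgb_subsample: tuple = (0.6, 0.8, 1.0)
    xgb_min_child_weight: tuple = (1, 3, 5)
    xgb_colsample: tuple = (0.6, 0.8, 1.0)
    xgb_n_estimators: int = 100
    cv_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for name in ("svr_C_grid", "svr_gamma_grid", "rf_mtry_grid", "xgb_learning_rate",
                     "xgb_max_depth", "xgb_gamma", "xgb_subsample",
                     "xgb_min_child_weight", "xgb_colsample"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be nonempty")

    def grid(self):
        """List of (label, estimator-factory kwargs) combinations."""
        if self.algorithm == "SVR":
            return [
                {"C": C, "gamma": g}
                for C, g in itertools.product(self.svr_C_grid, self.svr_gamma_grid)
            ]
        if self.algorithm == "RF":
            return [{"max_features": m} for m in self.rf_mtry_grid]
        if self.algorithm == "XGB":
            keys = ("learning_rate", "max_depth", "gamma", "subsample",
                    "min_child_weight", "colsample_bytree")
            grids = (self.xgb_learning_rate, self.xgb_max_depth, self.xgb_gamma,
                     self.xgb_subsample, self.xgb_min_child_weight, self.xgb_colsample)
            return [dict(zip(keys, combo)) for combo in itertools.product(*grids)]
        return [{}]  # STEPWISE has no grid

    def make_estimator(self, params: dict):
        if self.algorithm == "SVR":
            return SVR(kernel="rbf", **params)
        if self.algorithm == "RF":
            return RandomForestRegressor(
                n_estimators=self.rf_trees, random_state=self.seed, n_jobs=1, **params
            )
        if self.algorithm == "XGB":
            return XGBRegressor(
                n_estimators=self.xgb_n_estimators, random_state=self.seed,
                n_jobs=1, verbosity=0, **params,
            )
        raise ValueError("STEPWISE is fitted by stepwise_aic, not a grid estimator")


@dataclass(frozen=True)
class StandardizationParams:
    """Training-derived per-feature means/SDs; zero-variance features dropped."""

    mean: pd.Series
    sd: pd.Series
    dropped: tuple = ()

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.mean.index)
        return (df[cols] - self.mean) / self.sd

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.mean.index)
        return df[cols] * self.sd + self.mean


# --------------------------------------------------------------------------
# split / standardize
# --------------------------------------------------------------------------


def split_data(table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0):
    """Random disjoint 80/20-style split; train size rounds half up."""
    n = len(table)
    if n < 10:
        raise InvalidSplitError("need at least 10 rows to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise InvalidSplitError("split leaves an empty subset")
    perm = np.random.default_rng(seed).permutation(n)
    train = table.iloc[perm[:n_train]].reset_index(drop=True)
    test = table.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


def standardize(train: pd.DataFrame, test: pd.DataFrame, feature_cols):
    """Zero-mean/unit-variance scaling fitted on the training subset only."""
    mean = train[list(feature_cols)].mean()
    sd = train[list(feature_cols)].std(ddof=0)
    dropped = tuple(sd.index[sd <= 1e-12 * (1.0 + mean.abs())])
    if dropped:
        logger.warning("dropping zero-variance features: %s", list(dropped))
    keep = [c for c in feature_cols if c not in dropped]
    params = StandardizationParams(mean=mean[keep], sd=sd[keep], dropped=dropped)
    return params.transform(train), params.transform(test), params


# --------------------------------------------------------------------------
# tuning and training
# --------------------------------------------------------------------------


def tune_and_train(spec: RegressionSpec, X_train: pd.DataFrame, y_train):
    """Exhaustive grid search with seeded K-fold CV; selection by mean CV RMSE.

    Returns ``(fitted model, cv_record)`` where ``cv_record`` lists every
    grid combination with its mean CV RMSE (NaN for failed fits, which are
    excluded from selection). The winner is refitted on the full training
    subset. STEPWISE delegates to :func:`stepwise_aic`.
    """
    y = np.asarray(y_train, dtype=float)
    if spec.algorithm == "STEPWISE":
        model, selected, trace = stepwise_aic(X_train, y)
        record = pd.DataFrame([{"params": {"selected": selected}, "cv_rmse": np.nan}])
        return model, record
    combos = spec.grid()
    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(X_train))
    rows = []
    for params in combos:
        try:
            errs = []
            for tr_idx, va_idx in folds:
                est = spec.make_estimator(params)
                est.fit(X_train.iloc[tr_idx].to_numpy(), y[tr_idx])
                pred = est.predict(X_train.iloc[va_idx].to_numpy())
                errs.append(float(np.sqrt(np.mean((y[va_idx] - pred) ** 2))))
            rows.append({"params": params, "cv_rmse": float(np.mean(errs))})
        except Exception as exc:  # noqa: BLE001 - failed grid points are recorded
            logger.warning("grid point %s failed: %s", params, exc)
            rows.append({"params": params, "cv_rmse": np.nan})
    record = pd.DataFrame(rows)
    if record["cv_rmse"].isna().all():
        raise RuntimeError("every grid point failed to fit")
    best = record.loc[record["cv_rmse"].idxmin(), "params"]
    model = spec.make_estimator(best)
    model.fit(X_train.to_numpy(), y)
    return model, record


# --------------------------------------------------------------------------
# stepwise AIC linear regression
# --------------------------------------------------------------------------


class LinearModel:
    """Ordinary least squares on a feature subset, with sklearn-style predict."""

    def __init__(self, features, coef, intercept):
        self.features_ = tuple(features)
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = float(intercept)

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[list(self.features_)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def _ols_aic(X: np.ndarray, y: np.ndarray):
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * (p + 1)
    return aic, beta


def stepwise_aic(X_train: pd.DataFrame, y_train):
    """Bidirectional stepwise selection under AIC = n log(RSS/n) + 2 (p + 1).

    Starting from the intercept-only model, each step takes the single add or
    drop with the largest AIC decrease, stopping when no move improves.
    Exact duplicate columns are removed up front (with a warning). Returns
    ``(LinearModel, selected features, step trace)``.
    """
    y = np.asarray(y_train, dtype=float)
    cols = list(X_train.columns)
    # drop exact duplicates (collinearity guard)
    seen, kept = {}, []
    for c in cols:
        key = tuple(np.round(X_train[c].to_numpy(dtype=float), 12))
        if key in seen:
            logger.warning("dropping duplicate feature column %r (== %r)", c, seen[key])
            continue
        seen[key] = c
        kept.append(c)
    selected: list = []
    current_aic, _ = _ols_aic(np.empty((len(y), 0)), y)
    trace = [("start", None, current_aic)]
    while True:
        moves = []
        for c in kept:
            if c in selected:
                cand = [f for f in selected if f != c]
                move = ("drop", c)
            else:
                cand = selected + [c]
                move = ("add", c)
            aic, _ = _ols_aic(X_train[cand].to_numpy(dtype=float), y)
            moves.append((aic, move, cand))
        moves.sort(key=lambda m: m[0])
        best_aic, best_move, best_set = moves[0]
        if best_aic >= current_aic - 1e-10:
            break
        current_aic, selected = best_aic, best_set
        trace.append((*best_move, best_aic))
    _, beta = _ols_aic(X_train[selected].to_numpy(dtype=float), y)
    model = LinearModel(selected, beta[1:], beta[0])
    return model, tuple(selected), trace


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


def evaluate(y_true, y_pred) -> dict:
    """R^2 (about the test mean) and RMSE in g/plant on the response scale."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return {"r2": float("nan"), "rmse": rmse, "n": len(y_true), "r2_undefined": True}
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return {"r2": 1.0 - ss_res / ss_tot, "rmse": rmse, "n": len(y_true), "r2_undefined": False}


def subgroup_report(
    y_true, y_pred, metadata: pd.DataFrame, grouping_keys, min_n: int = 3
) -> pd.DataFrame:
    """Post-hoc per-group accuracy of predictions made once on the full test set.

    One row per group per grouping key: n, R^2, RMSE, and the slope/intercept
    of observed regressed on predicted. Groups with fewer than ``min_n`` rows
    get their metrics suppressed (NaN) and flagged.
    """
    df = metadata.reset_index(drop=True).copy()
    df["_y"] = np.asarray(y_true, dtype=float)
    df["_yhat"] = np.asarray(y_pred, dtype=float)
    rows = []
    n_suppressed = 0
    for key in grouping_keys:
        for level, sub in df.groupby(key, sort=True):
            if len(sub) < min_n:
                n_suppressed += 1
                rows.append(
                    {"key": key, "group": level, "n": len(sub), "r2": np.nan,
                     "rmse": np.nan, "slope": np.nan, "intercept": np.nan,
                     "suppressed": True}
                )
                continue
            metrics = evaluate(sub["_y"], sub["_yhat"])
            if np.ptp(sub["_yhat"].to_numpy()) > 0:
                slope, intercept = np.polyfit(sub["_yhat"], sub["_y"], 1)
            else:
                slope, intercept = np.nan, np.nan
            rows.append(
                {"key": key, "group": level, "n": len(sub), "r2": metrics["r2"],
                 "rmse": metrics["rmse"], "slope": float(slope),
                 "intercept": float(intercept), "suppressed": False}
            )
    if n_suppressed:
        logger.warning("%d subgroups below n = %d suppressed", n_suppressed, min_n)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Shapley attributions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapTable:
    """Per-sample per-feature Shapley attributions with the baseline value.

    Additivity: ``baseline + values.sum(axis=1) == model prediction`` (exact
    for the linear explainer; exact up to floating point for the permutation
    estimator since each permutation's contributions telescope).
    """

    values: pd.DataFrame  # (n_samples, n_features)
    baseline: float
    model_id: str
    method: str


def shap_attributions(
    model,
    background: pd.DataFrame,
    X: pd.DataFrame,
    seed: int = 0,
    method: str = "auto",
    n_permutations: int = 20,
    model_id: str = "",
) -> ShapTable:
    """Shapley attributions of predictions on ``X``.

    ``method="linear"`` (automatic for :class:`LinearModel`) uses the closed
    form ``phi_j = beta_j (x_j - mean background_j)`` over the model's
    selected features. ``method="permutation"`` averages marginal
    contributions over ``n_permutations`` seeded feature orderings, valuing a
    coalition by the mean prediction with absent features drawn from the
    background sample. The baseline is the mean background prediction.
    """
    if len(background) == 0:
        raise ValueError("background sample must be nonempty")
    if method == "auto":
        method = "linear" if isinstance(model, LinearModel) else "permutation"
    features = list(X.columns)
    if method == "linear":
        if not isinstance(model, LinearModel):
            raise TypeError("linear explainer requires a LinearModel")
        phi = pd.DataFrame(0.0, index=range(len(X)), columns=features)
        bg_mean = background[list(model.features_)].mean()
        for j, f in enumerate(model.features_):
            phi[f] = model.coef_[j] * (X[f].to_numpy(dtype=float) - bg_mean[f])
        baseline = float(model.predict(background).mean())
        return ShapTable(values=phi, baseline=baseline, model_id=model_id, method="linear")

    if method != "permutation":
        raise ValueError(f"unknown SHAP method {method!r}")
    rng = np.random.default_rng(seed)
    bg = background[features].to_numpy(dtype=float)
    Xv = X[features].to_numpy(dtype=float)
    n, d = Xv.shape
    nb = len(bg)
    phi = np.zeros((n, d))
    baseline = float(np.mean(model.predict(bg)))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        # composite matrices: start from every background row, reveal features
        # of x in permutation order; v(S) = mean prediction over backgrounds
        for i in range(n):
            batch = np.empty(((d + 1) * nb, d))
            batch[:nb] = bg
            cur = bg.copy()
            for step, j in enumerate(order):
                cur[:, j] = Xv[i, j]
                batch[(step + 1) * nb : (step + 2) * nb] = cur
            preds = np.asarray(model.predict(batch), dtype=float).reshape(d + 1, nb).mean(axis=1)
            contrib = np.diff(preds)
            for step, j in enumerate(order):
                phi[i, j] += contrib[step]
    phi /= n_permutations
    return ShapTable(
        values=pd.DataFrame(phi, columns=features), baseline=baseline,
        model_id=model_id, method="permutation",
    )


# --------------------------------------------------------------------------
# end-to-end convenience for one view / algorithm
# --------------------------------------------------------------------------

FEATURE_COLUMNS = ("A_proj", "GRVI", "GLI", "VARI", "GSI", "H_max", "H_ave")


def run_regression(
    features: pd.DataFrame,
    biomass: pd.DataFrame,
    spec: RegressionSpec,
    view: str,
    grouping_keys=("year", "dap", "treatment", "genotype_id"),
    with_shap: bool = False,
    shap_background: int = 100,
) -> dict:
    """Join features and biomass for one view, train, evaluate, attribute.

    Rows with missing features are dropped (logged). Returns a dict with the
    fitted model, standardization parameters, CV record, overall and subgroup
    evaluation, and (optionally) the SHAP table on the test subset.
    """
    sub = features[features["view"] == view].merge(
        biomass[["plant_id", "shoot_dry_weight_g"]], on="plant_id", how="inner"
    )
    n0 = len(sub)
    sub = sub.dropna(subset=[*FEATURE_COLUMNS, "shoot_dry_weight_g"]).reset_index(drop=True)
    if len(sub) < n0:
        logger.warning("dropped %d rows with missing values before modeling", n0 - len(sub))
    train, test = split_data(sub, spec.train_fraction, spec.seed)
    X_train, X_test, scaler = standardize(train, test, FEATURE_COLUMNS)
    y_train = train["shoot_dry_weight_g"].to_numpy(dtype=float)
    y_test = test["shoot_dry_weight_g"].to_numpy(dtype=float)
    model, cv_record = tune_and_train(spec, X_train, y_train)
    y_pred = np.asarray(model.predict(X_test if isinstance(model, LinearModel) else X_test.to_numpy()))
    overall = evaluate(y_test, y_pred)
    keys = [k for k in grouping_keys if k in test.columns]
    subgroups = subgroup_report(y_test, y_pred, test[keys], keys)
    out = {
        "view": view, "algorithm": spec.algorithm, "model": model, "scaler": scaler,
        "cv_record": cv_record, "overall": overall, "subgroups": subgroups,
        "y_test": y_test, "y_pred": np.asarray(y_pred, dtype=float),
        "test_meta": test[keys + ["plant_id"]],
    }
    if with_shap:
        bg = X_train.iloc[: min(shap_background, len(X_train))]
        out["shap"] = shap_attributions(
            model, bg, X_test, seed=spec.seed,
            model_id=f"{spec.algorithm}:{view}",
        )
    return out
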