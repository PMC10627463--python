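"""Stochastic gradient-boosted classification trees with stepwise sizing.

Occurrence-state (presence / likely absence) is fitted by stagewise
Bernoulli-deviance boosting of shallow trees with shrinkage and per-tree
bagging. The number of trees is not fixed a priori: trees are added
``step_size`` at a time while mean holdout deviance over stratified
cross-validation folds is tracked, and the count minimizing that deviance
is selected (stopping after the minimum has been passed for a patience
window). Reported outputs are the cross-validated AUC (mean of per-fold
holdout AUCs), training AUC, selected tree count, per-predictor relative
influence (percent, summing to 100), and mean-centered partial-dependence
curves.

The boosting core is sklearn's ``GradientBoostingClassifier`` (binomial
deviance, ``learning_rate`` shrinkage, ``max_depth`` interaction depth,
``subsample`` bagging); the stepwise search, fold orchestration and curve
extraction live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "BRTConfig",
    "BRTFit",
    "fit_brt_step",
    "cross_validated_auc",
    "variable_importance",
    "partial_dependence",
    "run_replicates",
]


@dataclass(frozen=True)
class BRTConfig:
    """Boosting hyperparameters and the stepwise-search policy."""

    learning_rate: float = 0.001
    tree_complexity: int = 5  # maximum interaction depth per tree
    bag_fraction: float = 0.75  # per-tree resampling fraction
    n_folds: int = 10
    step_size: int = 50  # trees added per search increment
    max_trees: int = 10000
    patience: int = 5  # increments past the deviance minimum before stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.step_size < 1 or self.max_trees < self.step_size:
            raise ValueError("need step_size >= 1 and max_trees >= step_size")


@dataclass
class BRTFit:
    """One fitted model and its evaluation summary."""

    n_trees: int
    auc_train: float
    auc_cv: float
    relative_influence: pd.Series  # percent per predictor, sums to 100
    partial_dependence: dict = field(default_factory=dict)
    deviance_trace: pd.DataFrame | None = None  # tree count vs mean CV deviance
    model: GradientBoostingClassifier | None = None
    feature_names: list[str] = field(default_factory=list)
    X: pd.DataFrame | None = None


def _bernoulli_deviance(y: np.ndarray, raw: np.ndarray) -> float:
    # raw is the log-odds score; -2 * mean Bernoulli log-likelihood
    return float(-2.0 * np.mean(y * raw - np.logaddexp(0.0, raw)))


def _gbc(config: BRTConfig, n_estimators: int, random_state: int, warm: bool = False):
    return GradientBoostingClassifier(
        learning_rate=config.learning_rate,
        max_depth=config.tree_complexity,
        subsample=config.bag_fraction,
        n_estimators=n_estimators,
        random_state=random_state,
        warm_start=warm,
    )


def fit_brt_step(
    predictors: pd.DataFrame,
    response: np.ndarray | pd.Series,
    config: BRTConfig,
    pd_grid_size: int = 50,
) -> BRTFit:
    """Fit a boosted-tree occurrence model with stepwise tree selection.

    ``predictors`` holds one row per labelled patch; ``response`` the 0/1
    occurrence-state. Folds are stratified by class. The run is fully
    determined by ``config.seed``.
    """
    X = predictors.copy()
    y = np.asarray(response, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("predictors/response contain missing values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("response has a single class; cannot fit")
    if len(y) < config.n_folds:
        raise ValueError("fewer labelled patches than folds")

    ss = np.random.SeedSequence([config.seed, 11])
    states = ss.generate_state(config.n_folds + 1) % (2**31 - 1)
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=int(states[0])
    )
    folds = list(skf.split(X, y))
    fold_models = [
        _gbc(config, 0, int(states[k + 1]), warm=True) for k in range(len(folds))
    ]

    steps: list[int] = []
    mean_dev: list[float] = []
    holdout_raw: list[dict[int, np.ndarray]] = [dict() for _ in folds]
    best = np.inf
    worse_streak = 0
    n = config.step_size
    Xv = X.to_numpy()
    while n <= config.max_trees:
        devs = []
        for k, (tr, te) in enumerate(folds):
            m = fold_models[k]
            m.set_params(n_estimators=n)
            m.fit(Xv[tr], y[tr])
            raw = m.decision_function(Xv[te])
            holdout_raw[k][n] = raw
            devs.append(_bernoulli_deviance(y[te], raw))
        steps.append(n)
        mean_dev.append(float(np.mean(devs)))
        if mean_dev[-1] < best - 1e-12:
            best = mean_dev[-1]
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= config.patience:
                break
        n += config.step_size

    n_trees = steps[int(np.argmin(mean_dev))]
    fold_predictions = [
        (holdout_raw[k][n_trees], y[te]) for k, (tr, te) in enumerate(folds)
    ]
    auc_cv = cross_validated_auc(fold_predictions)

    final = _gbc(config, n_trees, int(states[0]))
    final.fit(Xv, y)
    auc_train = float(roc_auc_score(y, final.decision_function(Xv)))
    influence = variable_importance(final, list(X.columns))
    # pd_grid_size = 0 skips the (expensive) curves, e.g. in replicate sweeps
    pdp = {
        name: partial_dependence(final, X, name, grid_size=pd_grid_size)
        for name in X.columns
    } if pd_grid_size else {}
    return BRTFit(
        n_trees=n_trees,
        auc_train=auc_train,
        auc_cv=auc_cv,
        relative_influence=influence,
        partial_dependence=pdp,
        deviance_trace=pd.DataFrame({"n_trees": steps, "cv_deviance": mean_dev}),
        model=final,
        feature_names=list(X.columns),
        X=X,
    )


def cross_validated_auc(fold_predictions) -> float:
    """Mean of per-fold holdout AUCs (rank-based, ties counted 0.5).

    ``fold_predictions`` is a sequence of (scores, labels) pairs, one per
    fold; folds containing a single class are skipped with a warning.
    """
    aucs = []
    for scores, labels in fold_predictions:
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            warnings.warn("fold with a single class skipped in AUC-cv")
            continue
        aucs.append(roc_auc_score(labels, scores))
    if not aucs:
        raise ValueError("no fold had both classes; AUC-cv undefined")
    return float(np.mean(aucs))


def variable_importance(
    model: GradientBoostingClassifier, feature_names: list[str]
) -> pd.Series:
    """Relative influence (%) per predictor: split-improvement share x 100."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:  # no split anywhere (all-stump degenerate fit)
        imp = np.full_like(imp, 1.0 / len(imp))
        total = 1.0
    return pd.Series(imp / total * 100.0, index=feature_names, name="influence")


def partial_dependence(
    model: GradientBoostingClassifier,
    X: pd.DataFrame,
    predictor: str,
    grid_size: int = 50,
) -> pd.DataFrame:
    """Mean-centered partial dependence of the link-scale score.

    Evaluates the model with ``predictor`` fixed at each of ``grid_size``
    values spanning its observed range while all other predictors keep
    their observed joint values, averages the raw (log-odds) score, and
    subtracts the curve's mean.
    """
    if predictor not in X.columns:
        raise KeyError(f"unknown predictor {predictor!r}")
    col = X[predictor].to_numpy(dtype=float)
    grid = np.linspace(col.min(), col.max(), grid_size)
    Xw = X.to_numpy(dtype=float).copy()
    j = list(X.columns).index(predictor)
    fit = np.empty(grid_size)
    for k, v in enumerate(grid):
        Xw[:, j] = v
        fit[k] = float(np.mean(model.decision_function(Xw)))
    fit -= fit.mean()
    return pd.DataFrame({"value": grid, "fit": fit})


def run_replicates(
    predictors: pd.DataFrame,
    response,
    config: BRTConfig,
    n_replicates: int = 100,
    pd_grid_size: int = 0,
    keep_models: bool = False,
):
    """Repeat the stepwise fit with distinct derived seeds.

    Replicates differ only in their stochastic elements (bagging and fold
    assignment); the data are fixed. Returns a per-replicate summary
    DataFrame (auc_cv, auc_train, n_trees, one influence column per
    predictor) and, unless ``keep_models``, drops the fitted models.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    fits = []
    for r in range(n_replicates):
        sub_seed = int(np.random.SeedSequence([config.seed, 17, r]).generate_state(1)[0] % (2**31 - 1))
        rep_config = BRTConfig(
            learning_rate=config.learning_rate,
            tree_complexity=config.tree_complexity,
            bag_fraction=config.bag_fraction,
            n_folds=config.n_folds,
            step_size=config.step_size,
            max_trees=config.max_trees,
            patience=config.patience,
            seed=sub_seed,
        )
        fit = fit_brt_step(predictors, response, rep_config, pd_grid_size=pd_grid_size)
        row = {
            "replicate": r,
            "auc_cv": fit.auc_cv,
            "auc_train": fit.auc_train,
            "n_trees": fit.n_trees,
        }
        for name, val in fit.relative_influence.items():
            row[f"influence_{name}"] = val
        rows.append(row)
        if keep_models:
            fits.append(fit)
        else:
            fit.model = None
            fit.X = None
            fits.append(fit)
    return pd.DataFrame(rows), fits
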