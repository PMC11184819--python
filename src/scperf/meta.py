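"""Meta-models predicting pipeline performance from pipeline parameters and
dataset characteristics.

Two model families (random forest, elastic net) are tuned by grid search
under dataset-aware cross-validation: all rows of one dataset stay in one
fold, so cross-validated error reflects unseen datasets.  Two feature modes
are supported: *pipeline_only* (4 pipeline parameters, predictions shared by
all datasets) and *interactions* (dataset features alongside pipeline
parameters; for linear models explicit dataset x pipeline product terms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet

from .engine import PipelineGrid, encode_pipeline_grid

__all__ = [
    "ModelInput",
    "SplitSpec",
    "TunedModel",
    "assemble_features",
    "dataset_aware_split",
    "dataset_aware_cv_folds",
    "tune_random_forest",
    "tune_elastic_net",
    "predict",
    "feature_importance",
    "NTREE_GRID",
    "ALPHA_GRID",
    "LAMBDA_GRID",
]

NTREE_GRID = (100, 300, 500)
ALPHA_GRID = (0.10, 0.55, 1.00)  # lasso-ridge mixing
LAMBDA_GRID = (0.001, 0.01, 0.1)  # penalty strength


@dataclass
class ModelInput:
    X: pd.DataFrame
    y: pd.Series
    groups: np.ndarray  # dataset_id per row
    mode: str
    metric: str


@dataclass
class SplitSpec:
    train_ids: list
    test_ids: list
    forced_test_ids: list


@dataclass
class TunedModel:
    kind: str
    mode: str
    metric: str
    params: dict
    cv_rmse: pd.DataFrame
    model: object
    feature_names: list = field(default_factory=list)


def assemble_features(
    features: pd.DataFrame,
    grid: PipelineGrid,
    table: pd.DataFrame,
    mode: str,
    metric: str,
    model_kind: str = "random_forest",
) -> ModelInput:
    """Build the model matrix for dataset x pipeline rows of ``table``.

    ``pipeline_only``: the 4 pipeline parameters (categorical codes +
    numerics).  ``interactions``: dataset features plus pipeline parameters;
    linear models use one-hot pipeline encoding and append the full outer
    product of dataset features with pipeline columns.
    Target column: ``{metric}_corrected`` (falling back to ``_scaled``).
    """
    if mode not in ("pipeline_only", "interactions"):
        raise ValueError("mode must be 'pipeline_only' or 'interactions'")
    ycol = f"{metric}_corrected" if f"{metric}_corrected" in table else f"{metric}_scaled"
    if ycol not in table:
        raise KeyError(f"no target column for metric {metric!r}")
    if table.duplicated(["dataset_id", "pipeline_id"]).any():
        raise ValueError("duplicate dataset/pipeline rows")

    style = "linear" if (model_kind == "elastic_net" and mode == "interactions") else "tree"
    enc = encode_pipeline_grid(grid, style=style)
    unknown = set(table["pipeline_id"]) - set(enc.index)
    if unknown:
        raise KeyError(f"unknown pipeline ids: {sorted(unknown)[:3]}")
    if style == "tree":  # standardize numerics so scales are comparable
        for col in ("n_dims", "resolution"):
            v = enc[col]
            sd = v.std(ddof=1)
            enc[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)

    P = enc.loc[table["pipeline_id"]].reset_index(drop=True)
    if mode == "pipeline_only":
        X = P
    else:
        missing = set(table["dataset_id"]) - set(features.index)
        if missing:
            raise KeyError(f"datasets without features: {sorted(missing)[:3]}")
        D = features.loc[table["dataset_id"]].reset_index(drop=True)
        parts = [D, P]
        if style == "linear":
            inter = {}
            for dcol in D.columns:
                dv = D[dcol].to_numpy()
                for pcol in P.columns:
                    inter[f"{dcol}*{pcol}"] = dv * P[pcol].to_numpy()
            parts.append(pd.DataFrame(inter))
        X = pd.concat(parts, axis=1)
    y = table[ycol].reset_index(drop=True)
    if y.isna().any():
        raise ValueError("target contains missing values; impute first")
    return ModelInput(
        X=X, y=y.rename(metric), groups=table["dataset_id"].to_numpy(object), mode=mode, metric=metric
    )


def dataset_aware_split(
    dataset_ids, labeled_ids=(), test_frac: float = 0.3, seed: int = 0
) -> SplitSpec:
    """70/30-style split at the dataset level; labeled datasets are forced
    into the test set so predictions can be compared with reference labels."""
    ids = list(dataset_ids)
    labeled = list(labeled_ids)
    if set(labeled) - set(ids):
        raise ValueError("labeled ids must be a subset of dataset ids")
    n_test = math.floor(test_frac * len(ids))
    if len(labeled) > n_test:
        raise ValueError(f"{len(labeled)} labeled datasets exceed the test budget {n_test}")
    pool = [d for d in ids if d not in set(labeled)]
    rng = np.random.default_rng(seed)
    fill = list(rng.choice(pool, size=n_test - len(labeled), replace=False)) if n_test > len(labeled) else []
    test = sorted(labeled + fill)
    train = sorted(set(ids) - set(test))
    return SplitSpec(train_ids=train, test_ids=test, forced_test_ids=sorted(labeled))


def dataset_aware_cv_folds(train_ids, k: int = 10, seed: int = 0) -> list[list]:
    """Balanced random partition of training datasets into ``k`` folds."""
    ids = list(train_ids)
    if k > len(ids):
        raise ValueError("more folds than training datasets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds: list[list] = [[] for _ in range(k)]
    for i, j in enumerate(perm):
        folds[i % k].append(ids[j])
    return [sorted(f) for f in folds]


def _cv_rmse(make_model, inp: ModelInput, folds: list[list]) -> float:
    errs = []
    for fold in folds:
        te = np.isin(inp.groups, fold)
        if not te.any() or te.all():
            continue
        m = make_model()
        m.fit(inp.X[~te], inp.y[~te])
        pred = m.predict(inp.X[te])
        errs.append((pred - inp.y[te].to_numpy()) ** 2)
    return float(np.sqrt(np.concatenate(errs).mean()))


def _default_mtry_grid(p: int) -> tuple:
    return tuple(sorted({1, math.ceil(p / 3), math.ceil(p / 2), p}))


def tune_random_forest(
    inp: ModelInput,
    folds: list[list],
    ntree_grid=NTREE_GRID,
    mtry_grid=None,
    seed: int = 0,
) -> TunedModel:
    """Grid-search ntree x mtry by dataset-aware CV RMSE, refit on all rows."""
    if inp.y.std(ddof=1) == 0:
        raise ValueError("degenerate target (zero variance)")
    p = inp.X.shape[1]
    if mtry_grid is None:
        mtry_grid = _default_mtry_grid(p)
    records = []
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            make = lambda: RandomForestRegressor(
                n_estimators=ntree, max_features=min(mtry, p), random_state=seed, n_jobs=1
            )
            records.append({"ntree": ntree, "mtry": mtry, "cv_rmse": _cv_rmse(make, inp, folds)})
    cv = pd.DataFrame(records)
    best = cv.loc[cv["cv_rmse"].idxmin()]
    model = RandomForestRegressor(
        n_estimators=int(best["ntree"]),
        max_features=min(int(best["mtry"]), p),
        random_state=seed,
        n_jobs=1,
    ).fit(inp.X, inp.y)
    return TunedModel(
        kind="random_forest",
        mode=inp.mode,
        metric=inp.metric,
        params={"ntree": int(best["ntree"]), "mtry": int(best["mtry"])},
        cv_rmse=cv,
        model=model,
        feature_names=list(inp.X.columns),
    )


def tune_elastic_net(
    inp: ModelInput,
    folds: list[list],
    alpha_grid=ALPHA_GRID,
    lambda_grid=LAMBDA_GRID,
    seed: int = 0,
) -> TunedModel:
    """Grid-search the lasso-ridge mixing (alpha) and penalty strength
    (lambda) by dataset-aware CV RMSE, refit on all rows."""
    if not np.isfinite(inp.X.to_numpy()).all() or not np.isfinite(inp.y.to_numpy()).all():
        raise ValueError("non-finite model inputs")
    records = []
    for a in alpha_grid:
        for lam in lambda_grid:
            make = lambda: ElasticNet(alpha=lam, l1_ratio=a, max_iter=20000, random_state=seed)
            records.append({"alpha": a, "lambda": lam, "cv_rmse": _cv_rmse(make, inp, folds)})
    cv = pd.DataFrame(records)
    best = cv.loc[cv["cv_rmse"].idxmin()]
    model = ElasticNet(
        alpha=float(best["lambda"]), l1_ratio=float(best["alpha"]), max_iter=20000, random_state=seed
    ).fit(inp.X, inp.y)
    return TunedModel(
        kind="elastic_net",
        mode=inp.mode,
        metric=inp.metric,
        params={"alpha": float(best["alpha"]), "lambda": float(best["lambda"])},
        cv_rmse=cv,
        model=model,
        feature_names=list(inp.X.columns),
    )


def predict(model: TunedModel, inp: ModelInput | pd.DataFrame) -> np.ndarray:
    X = inp.X if isinstance(inp, ModelInput) else inp
    if list(X.columns) != model.feature_names:
        raise ValueError("feature layout does not match the fitted model")
    return np.asarray(model.model.predict(X), dtype=float)


def feature_importance(model: TunedModel) -> pd.Series:
    """Impurity-decrease importances (random forest) or absolute
    coefficients (elastic net), indexed by feature name."""
    m = model.model
    if model.kind == "random_forest":
        if not hasattr(m, "feature_importances_"):
            raise ValueError("model is not fitted")
        vals = m.feature_importances_
    else:
        if not hasattr(m, "coef_"):
            raise ValueError("model is not fitted")
        vals = np.abs(m.coef_)
    return pd.Series(vals, index=model.feature_names).sort_values(ascending=False)
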