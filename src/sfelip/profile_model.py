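"""Supervised prediction of log-recovery from descriptors, conditions and IDAC.

The regression dataset has one row per (lipid, condition) cell: 29 pruned
molecular descriptors + temperature, pressure, ethanol flow (+ optionally the
infinite-dilution activity coefficient), with target y = log10 relative
abundance.  Zero-abundance (below-detection) cells are imputed at y = -7,
one log-decade below the smallest detectable abundance, and flagged.

Protocol: all rows of one held-out condition (default SC5) form the
*validation* split — generalisation to an unseen operating point; the rest is
split 80:20 into train/test; hyperparameters are tuned by grid search with
5-fold cross-validation on the training split; each model is evaluated with
MSE/RMSE/MAE/R^2 per split, and the whole protocol is run with and without
the IDAC column (the ablation that probes whether the thermodynamic feature
helps or merely duplicates descriptor information).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .io_core import ExtractionCondition, RecoveryTable, ValidationError, get_logger

__all__ = [
    "CENSOR_LOG_VALUE",
    "MODEL_NAMES",
    "DEFAULT_GRIDS",
    "FeatureTable",
    "SplitSpec",
    "ModelReport",
    "assemble_dataset",
    "split_dataset",
    "make_model",
    "tune_and_train",
    "evaluate",
    "ablation_idac",
    "feature_redundancy_report",
    "predict_profile",
    "reports_to_frame",
]

log = get_logger("profile_model")

#: Imputed log10 recovery for below-detection cells: lower than the smallest
#: detected abundance so censored cells stay separable from real signal.
CENSOR_LOG_VALUE = -7.0

CONDITION_FEATURES = ("temperature", "pressure", "ethanol_flow")
IDAC_COLUMN = "idac"

MODEL_NAMES = ("lasso", "gaussian_process", "svr", "random_forest", "xgboost", "ann")

#: Estimators that need standardized inputs; tree ensembles take raw features.
_SCALED_MODELS = frozenset({"lasso", "gaussian_process", "svr", "ann"})


@dataclass
class FeatureTable:
    """Feature matrix X, target y and censoring flags, row-aligned.

    X rows are indexed by a (lipid_id, condition_id) MultiIndex; columns are
    descriptor names, then the three condition variables, then optionally the
    IDAC column.
    """

    X: pd.DataFrame
    y: pd.Series
    censored_mask: pd.Series

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.censored_mask)):
            raise ValidationError("feature table rows misaligned")
        if self.X.isna().any().any():
            raise ValidationError("feature matrix has missing values after assembly")
        if not np.all(self.y[self.censored_mask] == CENSOR_LOG_VALUE):
            raise ValidationError("censored rows must carry the imputed floor value")

    @property
    def has_idac(self) -> bool:
        return IDAC_COLUMN in self.X.columns

    def without_idac(self) -> "FeatureTable":
        if not self.has_idac:
            return self
        return FeatureTable(
            X=self.X.drop(columns=[IDAC_COLUMN]), y=self.y, censored_mask=self.censored_mask
        )

    def rows_for_condition(self, condition_id: str) -> np.ndarray:
        return self.X.index.get_level_values("condition_id") == condition_id


@dataclass(frozen=True)
class SplitSpec:
    """Validation hold-out and train/test split specification."""

    holdout_condition_id: str = "SC5"
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValidationError("test_fraction must be in (0, 1)")


@dataclass
class ModelReport:
    """Per-model metrics in the train/test/validation layout."""

    model_name: str
    idac_included: bool
    metrics: pd.DataFrame  # index: split, columns: MSE RMSE MAE R2 n
    hyperparameters: dict

    def __post_init__(self) -> None:
        if not np.allclose(self.metrics["RMSE"], np.sqrt(self.metrics["MSE"]), atol=1e-12):
            raise ValidationError("RMSE inconsistent with MSE")
        if (self.metrics["R2"] > 1.0 + 1e-12).any():
            raise ValidationError("R^2 above 1")


# ---------------------------------------------------------------------------
# Dataset assembly and splitting
# ---------------------------------------------------------------------------


def assemble_dataset(
    recovery: RecoveryTable,
    descriptors: pd.DataFrame,
    design: list[ExtractionCondition],
    idac_table: pd.DataFrame | None = None,
    log_base: float = 10.0,
) -> FeatureTable:
    """Build the supervised dataset from the recovery table.

    ``descriptors`` is indexed by lipid_id (cleaned, e.g. 29 columns);
    ``idac_table`` (optional) is lipid_id x condition_id.  Each recovery cell
    yields one row; exact-zero cells get y = -7 and a censoring flag.
    """
    by_id = {c.id: c for c in design}
    missing_conditions = [c for c in recovery.condition_ids if c not in by_id]
    if missing_conditions:
        raise ValidationError(f"conditions missing from design: {', '.join(missing_conditions)}")
    missing_lipids = [l for l in recovery.lipid_ids if l not in descriptors.index]
    if missing_lipids:
        raise ValidationError(f"lipids missing from descriptors: {', '.join(missing_lipids[:5])}")

    rows, ys, censored = [], [], []
    index = []
    for i, lipid_id in enumerate(recovery.lipid_ids):
        desc_row = descriptors.loc[lipid_id]
        for j, cond_id in enumerate(recovery.condition_ids):
            cond = by_id[cond_id]
            a = recovery.abundance[i, j]
            features = list(desc_row.to_numpy()) + [
                cond.temperature, cond.pressure, cond.ethanol_flow
            ]
            if idac_table is not None:
                try:
                    features.append(float(idac_table.loc[lipid_id, cond_id]))
                except KeyError:
                    raise ValidationError(
                        f"IDAC missing for ({lipid_id}, {cond_id})"
                    ) from None
            rows.append(features)
            index.append((lipid_id, cond_id))
            if a == 0.0:
                ys.append(CENSOR_LOG_VALUE)
                censored.append(True)
            else:
                ys.append(float(np.log(a) / np.log(log_base)))
                censored.append(False)
    columns = list(descriptors.columns) + list(CONDITION_FEATURES)
    if idac_table is not None:
        columns.append(IDAC_COLUMN)
    midx = pd.MultiIndex.from_tuples(index, names=["lipid_id", "condition_id"])
    return FeatureTable(
        X=pd.DataFrame(rows, index=midx, columns=columns),
        y=pd.Series(ys, index=midx, name="log_recovery"),
        censored_mask=pd.Series(censored, index=midx, name="censored"),
    )


def _subset(table: FeatureTable, mask: np.ndarray) -> FeatureTable:
    return FeatureTable(
        X=table.X[mask], y=table.y[mask], censored_mask=table.censored_mask[mask]
    )


def split_dataset(
    table: FeatureTable, spec: SplitSpec
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """(train, test, validation): validation = every row of the held-out
    condition; the rest split uniformly at random by ``spec.seed``."""
    val_mask = table.rows_for_condition(spec.holdout_condition_id)
    if not val_mask.any():
        raise ValidationError(
            f"holdout condition {spec.holdout_condition_id!r} absent from table"
        )
    rest_idx = np.flatnonzero(~val_mask)
    train_idx, test_idx = train_test_split(
        rest_idx, test_size=spec.test_fraction, random_state=spec.seed, shuffle=True
    )
    train_mask = np.zeros(len(table.X), dtype=bool)
    test_mask = np.zeros(len(table.X), dtype=bool)
    train_mask[train_idx] = True
    test_mask[test_idx] = True
    return _subset(table, train_mask), _subset(table, test_mask), _subset(table, val_mask)


# ---------------------------------------------------------------------------
# Model zoo, tuning, evaluation
# ---------------------------------------------------------------------------

#: Default hyperparameter grids, deliberately small and documented; override
#: per run.  Parameter names address the estimator step of the pipeline.
DEFAULT_GRIDS: dict[str, dict] = {
    "lasso": {"model__alpha": [1e-3, 1e-2, 1e-1, 1.0]},
    "gaussian_process": {"model__alpha": [1e-4, 1e-2]},
    "svr": {"model__C": [0.1, 1.0, 10.0]},
    "random_forest": {"model__max_depth": [None, 9], "model__n_estimators": [200]},
    "xgboost": {"model__max_depth": [3, 6, 9], "model__learning_rate": [0.05, 0.1, 0.3]},
    "ann": {"model__hidden_layer_sizes": [(32,), (64,), (64, 32)]},
}


def make_model(model_name: str, seed: int = 0) -> Pipeline:
    """Instantiate one estimator pipeline by name, fully seeded.

    Inputs are standardized for lasso/SVR/GP/ANN and passed raw to the tree
    ensembles; the GP kernel is RBF + white noise with a bounded length-scale
    to keep the marginal-likelihood fit away from degenerate optima.
    """
    if model_name == "lasso":
        model = Lasso(alpha=1e-2, max_iter=50_000, random_state=seed)
    elif model_name == "gaussian_process":
        kernel = RBF(length_scale=1.0, length_scale_bounds=(1e-1, 1e3)) + WhiteKernel(
            noise_level=1e-2, noise_level_bounds=(1e-6, 1e1)
        )
        model = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-4, normalize_y=True, random_state=seed
        )
    elif model_name == "svr":
        model = SVR(kernel="rbf", C=1.0, epsilon=0.05)
    elif model_name == "random_forest":
        model = RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    elif model_name == "xgboost":
        model = XGBRegressor(
            n_estimators=400,
            max_depth=6,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            tree_method="exact",
        )
    elif model_name == "ann":
        model = MLPRegressor(
            hidden_layer_sizes=(64,),
            max_iter=2000,
            early_stopping=True,
            n_iter_no_change=20,
            random_state=seed,
        )
    else:
        raise ValidationError(f"unknown model name {model_name!r}")
    steps = []
    if model_name in _SCALED_MODELS:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", model))
    return Pipeline(steps)


def tune_and_train(
    model_name: str,
    train: FeatureTable,
    grid: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[Pipeline, dict]:
    """Grid search (scored by CV RMSE) over ``grid``; best configuration is
    refit on the full training split.  A singleton grid skips cross-validation
    and is equivalent to a direct fit."""
    if grid is None:
        grid = DEFAULT_GRIDS[model_name]
    if any(len(v) == 0 for v in grid.values()):
        raise ValidationError(f"degenerate grid for {model_name!r}")
    pipe = make_model(model_name, seed=seed)
    X, y = train.X.to_numpy(), train.y.to_numpy()
    n_candidates = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_candidates <= 1:
        params = {k: v[0] for k, v in grid.items()}
        pipe.set_params(**params)
        pipe.fit(X, y)
        chosen = params
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            pipe, grid, cv=cv, scoring="neg_root_mean_squared_error", n_jobs=1, refit=True
        )
        search.fit(X, y)
        pipe = search.best_estimator_
        chosen = dict(search.best_params_)
    log.info("trained %s with %s", model_name, chosen)
    return pipe, chosen


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    if y_true.size == 0:
        raise ValidationError("empty split")
    resid = y_true - y_pred
    mse = float(np.mean(resid**2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return {
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "MAE": float(np.mean(np.abs(resid))),
        "R2": r2,
        "n": int(y_true.size),
    }


def evaluate(
    model: Pipeline,
    splits: dict[str, FeatureTable],
    model_name: str = "model",
    idac_included: bool | None = None,
    hyperparameters: dict | None = None,
) -> ModelReport:
    """MSE/RMSE/MAE/R^2 per split; R^2 uses each split's own mean baseline."""
    rows = {}
    for split_name, part in splits.items():
        pred = model.predict(part.X.to_numpy())
        rows[split_name] = _metrics(part.y.to_numpy(), pred)
    metrics = pd.DataFrame(rows).T[["MSE", "RMSE", "MAE", "R2", "n"]]
    if idac_included is None:
        idac_included = any(p.has_idac for p in splits.values())
    return ModelReport(
        model_name=model_name,
        idac_included=bool(idac_included),
        metrics=metrics,
        hyperparameters=hyperparameters or {},
    )


def run_protocol(
    table: FeatureTable,
    spec: SplitSpec,
    models: list[str] = list(MODEL_NAMES),
    grids: dict[str, dict] | None = None,
    seed: int = 0,
) -> tuple[list[ModelReport], dict[str, Pipeline]]:
    """Split -> tune -> evaluate for each requested model on one table."""
    train, test, validation = split_dataset(table, spec)
    splits = {"train": train, "test": test, "validation": validation}
    reports, fitted = [], {}
    for name in models:
        grid = (grids or {}).get(name, DEFAULT_GRIDS[name])
        model, chosen = tune_and_train(name, train, grid, seed=seed)
        reports.append(evaluate(model, splits, name, table.has_idac, chosen))
        fitted[name] = model
    return reports, fitted


def ablation_idac(
    table: FeatureTable,
    spec: SplitSpec,
    models: list[str] = list(MODEL_NAMES),
    grids: dict[str, dict] | None = None,
    seed: int = 0,
) -> list[ModelReport]:
    """Run the full protocol twice — with and without the IDAC column, same
    seeds — and return the paired reports (the +/- layout)."""
    if not table.has_idac:
        raise ValidationError("ablation requires a table with an IDAC column")
    with_reports, _ = run_protocol(table, spec, models, grids, seed)
    without_reports, _ = run_protocol(table.without_idac(), spec, models, grids, seed)
    return with_reports + without_reports


def feature_redundancy_report(
    table: FeatureTable, threshold: float = 0.75
) -> pd.DataFrame:
    """Pearson r of every feature against the IDAC column, sorted by |r|
    descending, flagging pairs above the descriptor-pruning threshold."""
    if not table.has_idac:
        raise ValidationError("table lacks an IDAC column")
    idac = table.X[IDAC_COLUMN]
    rows = []
    for col in table.X.columns:
        if col == IDAC_COLUMN:
            continue
        r = float(np.corrcoef(table.X[col], idac)[0, 1])
        rows.append((col, r, abs(r) > threshold))
    df = pd.DataFrame(rows, columns=["feature", "r", "flagged"])
    return df.reindex(df["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def predict_profile(
    model: Pipeline,
    condition: ExtractionCondition,
    lipid_features: pd.DataFrame,
    idac_values: pd.Series | None = None,
    floor_epsilon: float = 0.5,
) -> pd.DataFrame:
    """Predict the full lipid profile at one extraction condition.

    ``lipid_features`` holds one descriptor row per lipid (indexed by
    lipid_id).  Returns a DataFrame with predicted log10 recovery, the linear
    recovery 10^y, and a below_detection flag for predictions at or near the
    imputation floor (y <= -7 + ``floor_epsilon``).
    """
    X = lipid_features.copy()
    X["temperature"] = condition.temperature
    X["pressure"] = condition.pressure
    X["ethanol_flow"] = condition.ethanol_flow
    if idac_values is not None:
        X[IDAC_COLUMN] = idac_values
    expected = model.feature_names_in_ if hasattr(model, "feature_names_in_") else None
    n_expected = model.n_features_in_ if hasattr(model, "n_features_in_") else (
        model.named_steps["model"].n_features_in_
    )
    if X.shape[1] != n_expected:
        raise ValidationError(
            f"feature-set mismatch: model expects {n_expected} features, got {X.shape[1]}"
        )
    y = model.predict(X.to_numpy())
    return pd.DataFrame(
        {
            "log_recovery": y,
            "recovery": 10.0**y,
            "below_detection": y <= CENSOR_LOG_VALUE + floor_epsilon,
        },
        index=lipid_features.index,
    )


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Flatten ModelReports to one row per (model, idac) — the familiar
    metrics-table layout with MSE/RMSE/MAE/R^2 x train/test/validation."""
    rows = []
    for rep in reports:
        row: dict = {"model": rep.model_name, "idac": "+" if rep.idac_included else "-"}
        for split in rep.metrics.index:
            for metric in ("MSE", "RMSE", "MAE", "R2"):
                row[f"{metric}_{split}"] = rep.metrics.loc[split, metric]
        row["hyperparameters"] = repr(rep.hyperparameters)
        rows.append(row)
    return pd.DataFrame(rows)
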