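"""Surrogate metamodels: regressors mapping design parameters to exposure metrics.

One feed-forward network per (archetype, metric) pair, trained on Latin
Hypercube simulator runs, replaces per-dwelling physics simulation at stock
scale. Inputs are standardised; categorical inputs (terrain) enter one-hot
with a fixed level order. Heavy-tailed concentration targets (CO 8-h
maxima, spanning three decades of source strength) can be fitted on a
log1p scale and back-transformed at prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

#: fixed one-hot level order per categorical feature
CATEGORICAL_LEVELS = {"terrain": ("city", "urban", "rural")}

DEFAULT_HYPERPARAMS = {
    "hidden_layer_sizes": (64, 64),
    "activation": "relu",
    "solver": "adam",
    "max_iter": 1200,
    "early_stopping": True,
    "validation_fraction": 0.1,
    "n_iter_no_change": 30,
}


def encode_features(rows: pd.DataFrame, schema: list[str],
                    log_features: tuple = ()) -> np.ndarray:
    """Encode a feature frame against a fixed schema (continuous + one-hot).

    Features named in ``log_features`` enter as log1p — appropriate where
    the response is multiplicative in the input (e.g. emission rates
    spanning several decades). Raises on missing columns, NaNs, or unknown
    categorical levels (naming the offending level).
    """
    cols = []
    for name in schema:
        if name in CATEGORICAL_LEVELS:
            if name not in rows:
                raise ValueError(f"missing feature column {name!r}")
            vals = rows[name].to_numpy()
            levels = CATEGORICAL_LEVELS[name]
            unknown = set(vals) - set(levels)
            if unknown:
                raise ValueError(f"unknown {name} level: {sorted(unknown)!r}")
            for lv in levels:
                cols.append((vals == lv).astype(float))
        else:
            if name not in rows:
                raise ValueError(f"missing feature column {name!r}")
            x = rows[name].to_numpy(dtype=float)
            if np.any(~np.isfinite(x)):
                raise ValueError(f"non-finite values in feature {name!r}")
            cols.append(np.log1p(x) if name in log_features else x)
    return np.column_stack(cols)


@dataclass
class Metamodel:
    """A fitted surrogate for one archetype × metric."""

    archetype_id: str
    metric: str
    schema: list[str]
    pipeline: Pipeline
    log_features: tuple = ()
    log_target: bool = False
    clip: tuple[float, float] | None = None
    training_summary: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "Metamodel":
        return joblib.load(path)


def train_metamodel(design: pd.DataFrame, metrics: np.ndarray, *,
                    archetype_id: str = "", metric: str = "",
                    schema: list[str] | None = None,
                    hyperparams: dict | None = None, seed: int = 0,
                    log_target: bool = False, log_features: tuple = (),
                    clip: tuple[float, float] | None = None,
                    holdout_fraction: float = 0.2) -> Metamodel:
    """Fit a surrogate and record holdout quality.

    A ``holdout_fraction`` split is reserved for the reported R²/RMSE (the
    network additionally early-stops on its own internal validation split).
    Deterministic for a given seed.
    """
    y = np.asarray(metrics, dtype=float)
    if len(design) != len(y):
        raise ValueError("design and metrics length mismatch")
    if len(design) < 50:
        raise ValueError("need at least 50 training rows")
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite target values")
    schema = schema or list(design.columns)
    X = encode_features(design, schema, log_features)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=holdout_fraction,
                                              random_state=seed)
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("net", MLPRegressor(random_state=seed, **hp)),
    ])
    t = np.log1p(y_tr) if log_target else y_tr
    if np.std(t) < 1e-12:
        # degenerate constant target: a linear fit is exact and cheap
        from sklearn.linear_model import LinearRegression
        pipe = Pipeline([("scale", StandardScaler()), ("net", LinearRegression())])
    pipe.fit(X_tr, t)
    model = Metamodel(archetype_id, metric, schema, pipe,
                      log_features=tuple(log_features), log_target=log_target,
                      clip=clip)
    pred_te = _predict_encoded(model, X_te)
    model.training_summary = {
        "n_train": int(len(y_tr)),
        "n_holdout": int(len(y_te)),
        "holdout_r2": float(r2_score(y_te, pred_te)),
        "holdout_rmse": float(np.sqrt(mean_squared_error(y_te, pred_te))),
        "seed": int(seed),
    }
    if log_target:
        # heavy-tailed targets: quality on the (homoscedastic) log scale
        model.training_summary["holdout_r2_log"] = float(
            r2_score(np.log1p(y_te), np.log1p(np.maximum(pred_te, 0.0))))
    return model


def _predict_encoded(model: Metamodel, X: np.ndarray) -> np.ndarray:
    p = model.pipeline.predict(X)
    if model.log_target:
        p = np.expm1(p)
    if model.clip is not None:
        p = np.clip(p, *model.clip)
    return p


def predict_metrics(model: Metamodel, rows: pd.DataFrame) -> np.ndarray:
    """Predict the metric for stock parameter rows (order-preserving)."""
    X = encode_features(rows, model.schema, model.log_features)
    return _predict_encoded(model, X)


def evaluate_holdout(model: Metamodel, test_design: pd.DataFrame,
                     test_metrics) -> dict:
    """R² and RMSE of the surrogate on held-out simulated truth."""
    y = np.asarray(test_metrics, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 holdout rows")
    pred = predict_metrics(model, test_design)
    return {"r2": float(r2_score(y, pred)),
            "rmse": float(np.sqrt(mean_squared_error(y, pred)))}
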