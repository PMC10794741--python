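"""Stratified splitting and FDI regression (MLR, SVM, NN) with R²/RMSE/MAE.

Each cultivar group is split 7:3 into training and test sets by stratified
random sampling over FDI-quantile bins (largest-remainder allocation, so the
train total is exactly ``round(0.7 n)`` and every stratum keeps its
proportion within one plot).  Three regressors are fitted per feature source:

* MLR — ordinary least squares (minimum-norm solution with a warning when
  the design is rank deficient or has more features than rows);
* SVM — epsilon-insensitive linear support-vector regression, kernel scale 1
  realized as z-score standardization, box constraint and epsilon defaulting
  to the midpoints 0.19 / 0.019 of the protocol ranges;
* NN — one hidden layer of 10 tanh units trained with Levenberg-Marquardt
  and early stopping (see :mod:`frostfield.nnet`).

Accuracy: R² = 1 - SS_res/SS_tot, RMSE, MAE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .nnet import LMNetwork
from .rgb_features import RGB_FEATURE_NAMES
from .ms_features import MS_FEATURE_NAMES

logger = logging.getLogger(__name__)

SOURCES = ("RGB", "MSI", "MULTISOURCE")
ALGORITHMS = ("MLR", "SVM", "NN")
SOURCE_FEATURES = {
    "RGB": tuple(RGB_FEATURE_NAMES),
    "MSI": tuple(MS_FEATURE_NAMES),
    "MULTISOURCE": tuple(RGB_FEATURE_NAMES) + tuple(MS_FEATURE_NAMES),
}

__all__ = [
    "SOURCES", "ALGORITHMS", "SOURCE_FEATURES",
    "EvaluationMetrics", "LinearModel", "StandardizedModel", "ModelReport",
    "stratified_split", "fit_mlr", "fit_svm", "fit_nn", "evaluate",
    "run_cells",
]


# ---------------------------------------------------------------------------
# splitting

def stratified_split(
    fdi: pd.Series | np.ndarray,
    ratio: float = 0.7,
    n_strata: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each plot to train/test, stratified on FDI quantile bins.

    Returns a frame aligned with the input order: ``plot_index`` (positional),
    ``stratum`` and ``role``.  The train total equals ``round(ratio * n)``;
    within-stratum quotas use largest-remainder rounding (ties to the larger
    stratum, then to the lower stratum id), and membership within a stratum is
    a seeded shuffle.
    """
    y = np.asarray(fdi, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 plots to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n_strata = min(n_strata, n)

    strata = pd.qcut(y, q=n_strata, labels=False, duplicates="drop")
    strata = np.asarray(strata, dtype=int)
    stratum_ids, sizes = np.unique(strata, return_counts=True)

    n_train = int(round(ratio * n))
    ideal = ratio * sizes
    quota = np.floor(ideal).astype(int)
    remainder = n_train - quota.sum()
    if remainder > 0:
        frac = ideal - quota
        order = np.lexsort((stratum_ids, -sizes, -frac))  # frac desc, size desc
        quota[order[:remainder]] += 1
    elif remainder < 0:
        frac = ideal - quota
        order = np.lexsort((stratum_ids, sizes, frac))
        for k in order:
            if remainder == 0:
                break
            if quota[k] > 0:
                quota[k] -= 1
                remainder += 1

    rng = np.random.default_rng(seed)
    role = np.empty(n, dtype=object)
    for sid, q in zip(stratum_ids, quota):
        members = np.flatnonzero(strata == sid)
        members = rng.permutation(members)
        role[members[:q]] = "train"
        role[members[q:]] = "test"
    return pd.DataFrame(
        {"plot_index": np.arange(n), "stratum": strata, "role": role}
    )


# ---------------------------------------------------------------------------
# models

@dataclass
class LinearModel:
    """Ordinary least-squares fit: intercept + coefficients."""

    intercept: float
    coef: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coef


@dataclass
class StandardizedModel:
    """Wraps a regressor with train-set z-score standardization of X (and y
    for the network, for conditioning)."""

    inner: object
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float = 0.0
    y_sd: float = 1.0

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) / self.x_sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = self.inner.predict(self._transform(X))
        return z * self.y_sd + self.y_mean


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def fit_mlr(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Least-squares linear regression (deterministic; minimum-norm on
    rank-deficient designs, with a logged warning)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < min(A.shape) or n <= p:
        logger.warning(
            "MLR design is rank deficient or under-determined "
            "(n=%d, p=%d, rank=%d): minimum-norm solution", n, p, rank
        )
    return LinearModel(intercept=float(coef[0]), coef=coef[1:])


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 0.19,
    epsilon: float = 0.019,
) -> StandardizedModel:
    """Linear epsilon-SVR on z-scored features (kernel scale 1)."""
    if C <= 0 or epsilon < 0:
        raise ValueError("need C > 0 and epsilon >= 0")
    Xz, mean, sd = _standardize(X)
    svr = SVR(kernel="linear", C=C, epsilon=epsilon, tol=1e-5, max_iter=-1)
    svr.fit(Xz, np.asarray(y, float).ravel())
    return StandardizedModel(inner=svr, x_mean=mean, x_sd=sd)


def fit_nn(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    hidden: int = 10,
    weight_decay: float = 1e-3,
    max_iter: int = 200,
) -> StandardizedModel:
    """LM-trained network on z-scored features and response."""
    Xz, mean, sd = _standardize(X)
    y = np.asarray(y, dtype=float).ravel()
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    net = LMNetwork(
        hidden=hidden, weight_decay=weight_decay, max_iter=max_iter, seed=seed
    )
    net.fit(Xz, (y - y_mean) / y_sd)
    return StandardizedModel(
        inner=net, x_mean=mean, x_sd=sd, y_mean=y_mean, y_sd=y_sd
    )


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class EvaluationMetrics:
    r2: float
    rmse: float
    mae: float
    n: int


def evaluate(y_true, y_pred) -> EvaluationMetrics:
    """R² = 1 - SS_res/SS_tot, RMSE and MAE.  R² is NaN (flagged) when the
    observed values have zero variance."""
    y = np.asarray(y_true, dtype=float).ravel()
    yhat = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return EvaluationMetrics(r2=r2, rmse=rmse, mae=mae, n=y.size)


# ---------------------------------------------------------------------------
# the 3 groups x 3 sources x 3 algorithms experiment grid

@dataclass
class ModelReport:
    group: str
    source: str
    algorithm: str
    features: list[str]
    train: EvaluationMetrics
    test: EvaluationMetrics
    predictions: pd.DataFrame = field(repr=False, default=None)

    def to_record(self) -> dict:
        return {
            "group": self.group, "source": self.source,
            "algorithm": self.algorithm, "n_features": len(self.features),
            "train_r2": self.train.r2, "train_rmse": self.train.rmse,
            "train_mae": self.train.mae, "test_r2": self.test.r2,
            "test_rmse": self.test.rmse, "test_mae": self.test.mae,
            "n_train": self.train.n, "n_test": self.test.n,
        }


def _fit_predict(algorithm, X_train, y_train, X_test, nn_seed, svm_params, nn_params):
    if algorithm == "MLR":
        model = fit_mlr(X_train, y_train)
    elif algorithm == "SVM":
        model = fit_svm(X_train, y_train, **svm_params)
    elif algorithm == "NN":
        model = fit_nn(X_train, y_train, seed=nn_seed, **nn_params)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return model.predict(X_train), model.predict(X_test)


def run_cells(
    table: pd.DataFrame,
    selection_report: pd.DataFrame,
    sources: tuple[str, ...] = SOURCES,
    algorithms: tuple[str, ...] = ALGORITHMS,
    ratio: float = 0.7,
    n_strata: int = 5,
    split_seed: int = 0,
    nn_seed: int = 0,
    svm_params: dict | None = None,
    nn_params: dict | None = None,
    target_col: str = "fdi",
    color_col: str = "cultivar_color",
) -> tuple[list[ModelReport], list[dict]]:
    """Fit every (group, source, algorithm) cell.

    ``table`` is the plot feature table (plot_id, cultivar_color, fdi,
    features); ``selection_report`` is the output of
    :func:`frostfield.selection.select_features`.  Each group is split
    independently (one split reused across its sources and algorithms).
    Feature NaNs are imputed with the training-set median.  Returns
    ``(reports, skipped)`` where ``skipped`` records cells without any
    selected feature or groups too small to split.
    """
    svm_params = svm_params or {}
    nn_params = nn_params or {}

    frames = {"ALL": table}
    for color, sub in table.groupby(color_col, observed=True):
        frames[str(color).upper()] = sub

    groups = [g for g in ("ALL", "GREEN", "RED") if g in frames]
    reports: list[ModelReport] = []
    skipped: list[dict] = []

    for gi, group in enumerate(groups):
        sub = frames[group].reset_index(drop=True)
        if len(sub) < 3:
            skipped.append({"group": group, "reason": "group too small"})
            continue
        split = stratified_split(
            sub[target_col], ratio=ratio, n_strata=n_strata,
            seed=split_seed + gi,
        )
        train_rows = split["role"] == "train"
        if train_rows.sum() < 2 or (~train_rows).sum() < 2:
            skipped.append({
                "group": group,
                "reason": "train or test split below 2 plots",
            })
            continue
        sel = selection_report[
            (selection_report["group"] == group) & selection_report["selected"]
        ]
        selected = set(sel["feature"])

        for source in sources:
            feats = [f for f in SOURCE_FEATURES[source] if f in selected]
            feats = [f for f in feats if f in sub.columns]
            if not feats:
                skipped.append({
                    "group": group, "source": source,
                    "reason": "no selected feature",
                })
                continue
            X = sub[feats].to_numpy(dtype=float)
            y = sub[target_col].to_numpy(dtype=float)
            X_train, y_train = X[train_rows], y[train_rows]
            X_test, y_test = X[~train_rows], y[~train_rows]
            med = np.nanmedian(X_train, axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            X_train = np.where(np.isnan(X_train), med, X_train)
            X_test = np.where(np.isnan(X_test), med, X_test)

            for algorithm in algorithms:
                try:
                    yhat_train, yhat_test = _fit_predict(
                        algorithm, X_train, y_train, X_test,
                        nn_seed, svm_params, nn_params,
                    )
                except RuntimeError as exc:
                    skipped.append({
                        "group": group, "source": source,
                        "algorithm": algorithm, "reason": str(exc),
                    })
                    continue
                preds = pd.DataFrame({
                    "plot_id": sub["plot_id"],
                    "role": split["role"],
                    "fdi": y,
                    "fdi_pred": np.concatenate([yhat_train, yhat_test])[
                        np.argsort(np.concatenate([
                            np.flatnonzero(train_rows.to_numpy()),
                            np.flatnonzero(~train_rows.to_numpy()),
                        ]))
                    ],
                })
                reports.append(ModelReport(
                    group=group, source=source, algorithm=algorithm,
                    features=feats,
                    train=evaluate(y_train, yhat_train),
                    test=evaluate(y_test, yhat_test),
                    predictions=preds,
                ))
    return reports, skipped
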