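"""Model evaluation: in-sample fit, fixed hold-out, and resampling.

Three designs mirror how a small-cohort model is honestly assessed:

1. in-sample: train on all N rows and score on the same rows;
2. hold-out: a seeded random split (default 37 train / 10 validation for
   N = 47), normalization fitted on training rows only, validation
   predictors clipped into the training [0, 1] range;
3. resampling: hold-out repeated over many independent splits, collecting
   the training- and validation-RMSE distributions (each validation set is
   the complement of its training set).

RMSE is reported on the normalized response scale throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rbf_model import (
    MinMaxScaler,
    RatioTable,
    TrainResult,
    rmse,
    scan_cluster_counts,
    train_rbf,
)

logger = logging.getLogger("decostress")


@dataclass(frozen=True)
class SplitSpec:
    """A seeded train/validation partition of N rows."""

    n_train: int
    n_valid: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_valid < 1:
            raise ValueError("both train and validation sets need at least 1 row")


@dataclass(frozen=True)
class HoldoutResult:
    train_result: TrainResult
    validation_rmse: float  # normalized scale
    n_clusters: int
    train_rows: tuple[int, ...]
    valid_rows: tuple[int, ...]
    #: RMSE on the raw SDNN-ratio scale (the scale accuracy is defined on);
    #: equals the normalized RMSE times the training response range
    training_rmse_raw: float = float("nan")
    validation_rmse_raw: float = float("nan")


@dataclass(frozen=True)
class ResamplingResult:
    """Training/validation RMSE distributions over repeated random splits."""

    training_errors: np.ndarray
    validation_errors: np.ndarray
    cluster_counts: np.ndarray
    n_splits: int
    trials_per_split: int
    seed: int
    n_failed: int = 0
    #: same errors on the raw SDNN-ratio scale
    training_errors_raw: np.ndarray = field(default_factory=lambda: np.array([]))
    validation_errors_raw: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.training_errors))

    @property
    def mean_valid(self) -> float:
        return float(np.mean(self.validation_errors))

    @property
    def mean_train_raw(self) -> float:
        return float(np.mean(self.training_errors_raw))

    @property
    def mean_valid_raw(self) -> float:
        return float(np.mean(self.validation_errors_raw))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "split_id": np.arange(len(self.training_errors)),
                "n_clusters": self.cluster_counts,
                "train_rmse": self.training_errors,
                "valid_rmse": self.validation_errors,
                "train_rmse_raw": self.training_errors_raw,
                "valid_rmse_raw": self.validation_errors_raw,
            }
        )


def _normalized_arrays(
    table: RatioTable, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, MinMaxScaler, MinMaxScaler]:
    """Min-max scalers fitted on ``rows`` (all rows when None)."""
    pred_raw = table.predictors.to_numpy(dtype=float)
    resp_raw = table.response[:, None]
    fit_pred = pred_raw if rows is None else pred_raw[rows]
    fit_resp = resp_raw if rows is None else resp_raw[rows]
    pred_scaler = MinMaxScaler.fit(fit_pred, names=table.predictor_names)
    resp_scaler = MinMaxScaler.fit(fit_resp, names=("sdnn_ratio",))
    return pred_raw, resp_raw, pred_scaler, resp_scaler


def fit_in_sample(
    table: RatioTable,
    trials: int = 10_000,
    seed: int | None = None,
    n_clusters: int | None = None,
) -> tuple[TrainResult, float]:
    """Train on all rows and evaluate on the same rows.

    Returns the train result and the in-sample RMSE (identical to the
    training RMSE by construction). ``n_clusters=None`` selects the count
    from the K-means decay curve.
    """
    pred_raw, resp_raw, pred_scaler, resp_scaler = _normalized_arrays(table)
    g = pred_scaler.transform(pred_raw)
    y = resp_scaler.transform(resp_raw).ravel()
    if n_clusters is None:
        n_clusters = scan_cluster_counts(g, seed=seed).selected
    result = train_rbf(g, y, s=n_clusters, trials=trials, seed=seed)
    model = _attach_scalers(result.model, table, pred_scaler, resp_scaler)
    result = TrainResult(
        model=model, training_rmse=result.training_rmse,
        iterations=result.iterations, seed=result.seed, redraws=result.redraws,
    )
    return result, result.training_rmse


def _attach_scalers(model, table, pred_scaler, resp_scaler):
    from dataclasses import replace

    return replace(
        model,
        predictor_names=table.predictor_names,
        predictor_scaler=pred_scaler,
        response_scaler=resp_scaler,
    )


def split_rows(n: int, split: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded draw without replacement partitioning rows into train/valid."""
    if split.n_train + split.n_valid != n:
        raise ValueError(
            f"split {split.n_train}+{split.n_valid} does not partition {n} rows"
        )
    rng = np.random.default_rng(split.seed)
    perm = rng.permutation(n)
    return np.sort(perm[: split.n_train]), np.sort(perm[split.n_train :])


def fit_holdout(
    table: RatioTable,
    split: SplitSpec,
    trials: int = 100,
    n_clusters: int | None = None,
    normalize_on: str = "train",
) -> HoldoutResult:
    """Train on a seeded subset, score on the held-out complement.

    Normalization min/max are computed on training rows only (no leakage)
    and validation predictors falling outside that range are clipped into
    [0, 1]; ``normalize_on="all"`` reproduces the leaky alternative.
    The cluster count is re-selected on each training set unless given.
    """
    if normalize_on not in ("train", "all"):
        raise ValueError("normalize_on must be 'train' or 'all'")
    train_rows, valid_rows = split_rows(table.n, split)
    fit_rows = None if normalize_on == "all" else train_rows
    pred_raw, resp_raw, pred_scaler, resp_scaler = _normalized_arrays(table, fit_rows)

    g_train = pred_scaler.transform(pred_raw[train_rows])
    y_train = resp_scaler.transform(resp_raw[train_rows]).ravel()
    g_valid = pred_scaler.transform(pred_raw[valid_rows], clip=True)
    y_valid = resp_scaler.transform(resp_raw[valid_rows]).ravel()

    if n_clusters is None:
        n_clusters = scan_cluster_counts(g_train, seed=split.seed).selected
    result = train_rbf(g_train, y_train, s=n_clusters, trials=trials, seed=split.seed)
    valid_rmse = rmse(result.model.predict_normalized(g_valid), y_valid)
    model = _attach_scalers(result.model, table, pred_scaler, resp_scaler)
    result = TrainResult(
        model=model, training_rmse=result.training_rmse,
        iterations=result.iterations, seed=result.seed, redraws=result.redraws,
    )
    # denormalizing is affine, so raw-scale RMSE is the normalized RMSE times
    # the training response range — the scale the SDNN-ratio accuracy lives on
    resp_range = float(resp_scaler.maxs[0] - resp_scaler.mins[0])
    return HoldoutResult(
        train_result=result,
        validation_rmse=valid_rmse,
        n_clusters=n_clusters,
        train_rows=tuple(int(i) for i in train_rows),
        valid_rows=tuple(int(i) for i in valid_rows),
        training_rmse_raw=result.training_rmse * resp_range,
        validation_rmse_raw=valid_rmse * resp_range,
    )


def resampling_experiment(
    table: RatioTable,
    n_splits: int = 500,
    trials: int = 100,
    seed: int = 0,
    n_train: int | None = None,
    n_clusters: int | None = None,
) -> ResamplingResult:
    """Hold-out repeated over ``n_splits`` independent seeded splits.

    Defaults to the 37/10 split shape when N = 47, otherwise roughly 80/20.
    Individual split failures (e.g. a constant column in a training subset)
    are logged and excluded; the count is reported.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if n_train is None:
        n_train = 37 if table.n == 47 else max(2, int(round(table.n * 0.8)))
    n_valid = table.n - n_train

    split_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    train_err, valid_err, counts = [], [], []
    train_err_raw, valid_err_raw = [], []
    n_failed = 0
    for split_seed in split_seeds:
        spec = SplitSpec(n_train=n_train, n_valid=n_valid, seed=int(split_seed))
        try:
            res = fit_holdout(table, spec, trials=trials, n_clusters=n_clusters)
        except ValueError as exc:
            logger.warning("split with seed %d failed: %s", split_seed, exc)
            n_failed += 1
            continue
        train_err.append(res.train_result.training_rmse)
        valid_err.append(res.validation_rmse)
        train_err_raw.append(res.training_rmse_raw)
        valid_err_raw.append(res.validation_rmse_raw)
        counts.append(res.n_clusters)
    return ResamplingResult(
        training_errors=np.asarray(train_err),
        validation_errors=np.asarray(valid_err),
        cluster_counts=np.asarray(counts, dtype=int),
        n_splits=n_splits,
        trials_per_split=trials,
        seed=seed,
        n_failed=n_failed,
        training_errors_raw=np.asarray(train_err_raw),
        validation_errors_raw=np.asarray(valid_err_raw),
    )
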