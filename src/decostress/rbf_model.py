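"""Radial basis function network with stochastic centroid search.

The model predicts the post/pre SDNN ratio from post/pre ratios of eight
inflammatory and immune markers. All variables (predictors and response) are
min-max normalized to [0, 1]. The network is

    psi(x) = sum_j a_j * exp(-||x - M_j||^2 / (2 sigma^2)) + b,

with S centroids M_j drawn uniformly in the unit hypercube, one shared width

    sigma = Dmax / sqrt(2 S),        Dmax = max pairwise centroid distance,

and weights (a_1..a_S, b) obtained as the least-squares solution of the
N x (S+1) Gaussian design system — the Moore-Penrose pseudo-inverse solve.
Training repeats the centroid draw for a number of trials and keeps the model
with the lowest training RMSE.

The number of basis functions S is chosen from the K-means within-cluster sum
of squares WS_j: a power-law decay WS_j ~ WS_1 * j^(-eps) is fitted on the
log-log scale and the selected S is the smallest cluster count whose observed
WS falls at or below the fitted curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger("decostress")

#: The eight marker post/pre ratio predictors, in canonical order.
MARKER_NAMES = (
    "cd16_pct",
    "cd66b_mfi",
    "mpo_pct",
    "mpo_mfi",
    "annexin_pos",
    "mp_cd66b",
    "mp_cd31",
    "mp_cd41",
)

RESPONSE_NAME = "sdnn_ratio"

#: K-means restarts per cluster count; best objective kept.
KMEANS_RESTARTS = 10

#: Decay exponents below this are treated as "no cluster structure".
FLAT_DECAY_EPS = 0.05

MAX_CENTROID_REDRAWS = 100


# ---------------------------------------------------------------------------
# dataset container and normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioTable:
    """Per-subject post/pre ratios: marker predictors plus the SDNN response.

    Holds the raw (unnormalized) ratio matrix; normalization happens at fit
    time so that train/validation splits can normalize on training rows only.
    """

    subject_ids: tuple[str, ...]
    predictors: pd.DataFrame  # raw ratios, one column per marker
    response: np.ndarray  # raw SDNN ratios

    def __post_init__(self) -> None:
        response = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", response)
        if not (len(self.subject_ids) == len(self.predictors) == response.size):
            raise ValueError("subject_ids, predictors and response must align")
        if (self.predictors.to_numpy() <= 0).any() or (response <= 0).any():
            raise ValueError("all ratios must be strictly positive")

    @property
    def n(self) -> int:
        return int(self.response.size)

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.predictors.columns)

    def subset(self, rows: Sequence[int]) -> "RatioTable":
        rows = list(rows)
        return RatioTable(
            subject_ids=tuple(self.subject_ids[i] for i in rows),
            predictors=self.predictors.iloc[rows].reset_index(drop=True),
            response=self.response[rows],
        )


@dataclass(frozen=True)
class MinMaxScaler:
    """Column-wise min-max map to [0, 1] with exact inversion."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, raw: np.ndarray, names: Sequence[str] | None = None) -> "MinMaxScaler":
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        mins = raw.min(axis=0)
        maxs = raw.max(axis=0)
        constant = maxs == mins
        if constant.any():
            which = (
                [names[i] for i in np.flatnonzero(constant)]
                if names is not None
                else list(np.flatnonzero(constant))
            )
            raise ValueError(f"constant column(s) cannot be min-max normalized: {which}")
        return cls(mins=mins, maxs=maxs)

    def transform(self, raw: np.ndarray, clip: bool = False) -> np.ndarray:
        scaled = (np.asarray(raw, dtype=float) - self.mins) / (self.maxs - self.mins)
        if clip:
            out_of_range = (scaled < 0) | (scaled > 1)
            if out_of_range.any():
                logger.warning(
                    "%d value(s) outside the training min/max range were clipped to [0, 1]",
                    int(out_of_range.sum()),
                )
            scaled = np.clip(scaled, 0.0, 1.0)
        return scaled

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * (self.maxs - self.mins) + self.mins


def minmax_normalize(
    raw: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, MinMaxScaler]:
    """Min-max normalize every column of a raw matrix to [0, 1]."""
    names = list(raw.columns) if isinstance(raw, pd.DataFrame) else None
    arr = np.atleast_2d(np.asarray(raw, dtype=float))
    scaler = MinMaxScaler.fit(arr, names=names)
    return scaler.transform(arr), scaler


# ---------------------------------------------------------------------------
# network geometry and linear solve
# ---------------------------------------------------------------------------

def euclidean_distance_sq(x: np.ndarray, m: np.ndarray) -> float:
    """Squared Euclidean distance between a data point and one centroid."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != m.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {m.shape}")
    diff = x - m
    return float(diff @ diff)


def compute_sigma(centroids: np.ndarray) -> float:
    """Shared Gaussian width sigma = Dmax / sqrt(2 S).

    Dmax is the maximum pairwise Euclidean distance among the S centroids.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    s = centroids.shape[0]
    if s < 2:
        raise ValueError("need at least 2 centroids to compute sigma")
    diffs = centroids[:, None, :] - centroids[None, :, :]
    dmax = float(np.sqrt((diffs**2).sum(axis=-1)).max())
    if dmax == 0:
        raise ValueError("degenerate centroids: all identical (Dmax = 0)")
    return dmax / np.sqrt(2.0 * s)


def _sq_dists(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - centroids[None, :, :]
    return (diff**2).sum(axis=-1)


def design_matrix(
    points: np.ndarray, centroids: np.ndarray, sigma: float
) -> np.ndarray:
    """N x (S+1) Gaussian design: exp(-E_kj / (2 sigma^2)) plus a ones column."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    gauss = np.exp(-_sq_dists(points, centroids) / (2.0 * sigma**2))
    return np.hstack([gauss, np.ones((points.shape[0], 1))])


def solve_weights(theta: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares weights (a_1..a_S, b) of the design system theta @ W = y.

    Implemented as the minimum-norm least-squares solution (SVD-based),
    which coincides with the pseudo-inverse (theta^T theta)^-1 theta^T y
    whenever the normal equations are invertible and stays finite when they
    are not (a warning is logged in that case).
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("design matrix contains non-finite entries")
    w, _, rank, _ = np.linalg.lstsq(theta, y, rcond=None)
    if rank < theta.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d columns): minimum-norm solution used",
            rank, theta.shape[1],
        )
    return w[:-1], float(w[-1])


@dataclass(frozen=True)
class RBFNetwork:
    """Fitted network: centroids, one shared sigma, weights and bias.

    Operates on the normalized [0, 1] scale; the attached scalers map raw
    marker ratios in and raw SDNN-ratio predictions out.
    """

    centroids: np.ndarray  # S x n
    sigma: float
    weights: np.ndarray  # length S
    bias: float
    predictor_names: tuple[str, ...] = ()
    predictor_scaler: MinMaxScaler | None = None
    response_scaler: MinMaxScaler | None = None

    def __post_init__(self) -> None:
        centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        object.__setattr__(self, "centroids", centroids)
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.weights.size != centroids.shape[0]:
            raise ValueError("one weight per centroid required")

    @property
    def n_centroids(self) -> int:
        return int(self.centroids.shape[0])

    def predict_normalized(self, points: np.ndarray) -> np.ndarray:
        """psi(x) on the normalized scale for points in [0, 1]^n."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        theta = design_matrix(points, self.centroids, self.sigma)
        return theta @ np.concatenate([self.weights, [self.bias]])

    def predict_raw(self, raw_predictors: np.ndarray, clip: bool = True) -> np.ndarray:
        """Predict raw SDNN ratios from raw marker ratios."""
        if self.predictor_scaler is None or self.response_scaler is None:
            raise ValueError("model has no scalers attached; use predict_normalized")
        x = self.predictor_scaler.transform(
            np.atleast_2d(np.asarray(raw_predictors, dtype=float)), clip=clip
        )
        psi = self.predict_normalized(x)
        return self.response_scaler.inverse(psi[:, None]).ravel()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "centroids": self.centroids.tolist(),
            "sigma": self.sigma,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "predictor_names": list(self.predictor_names),
            "predictor_minmax": None
            if self.predictor_scaler is None
            else {
                "mins": self.predictor_scaler.mins.tolist(),
                "maxs": self.predictor_scaler.maxs.tolist(),
            },
            "response_minmax": None
            if self.response_scaler is None
            else {
                "mins": self.response_scaler.mins.tolist(),
                "maxs": self.response_scaler.maxs.tolist(),
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RBFNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)

        def scaler(block):
            if block is None:
                return None
            return MinMaxScaler(
                mins=np.asarray(block["mins"]), maxs=np.asarray(block["maxs"])
            )

        return cls(
            centroids=np.asarray(payload["centroids"]),
            sigma=float(payload["sigma"]),
            weights=np.asarray(payload["weights"]),
            bias=float(payload["bias"]),
            predictor_names=tuple(payload.get("predictor_names", ())),
            predictor_scaler=scaler(payload.get("predictor_minmax")),
            response_scaler=scaler(payload.get("response_minmax")),
        )


def predict(model: RBFNetwork, points: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RBFNetwork.predict_normalized`."""
    return model.predict_normalized(points)


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error between predictions and observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size == 0:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


# ---------------------------------------------------------------------------
# cluster-count selection
# ---------------------------------------------------------------------------

def kmeans_within_ss(points: np.ndarray, j: int, seed: int | None = None) -> float:
    """Minimized K-means within-cluster sum of squared distances for j clusters.

    Lloyd's algorithm with 10 restarts; the best objective is returned.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if not 1 <= j <= n:
        raise ValueError(f"cluster count {j} out of range [1, {n}]")
    km = KMeans(n_clusters=j, n_init=KMEANS_RESTARTS, random_state=seed)
    km.fit(points)
    return float(km.inertia_)


@dataclass(frozen=True)
class ClusterSelection:
    cluster_counts: tuple[int, ...]
    within_ss: tuple[float, ...]
    decay_exponent: float  # eps of WS_j ~ WS_1 * j^(-eps)
    selected: int


def select_cluster_count(within_ss: Sequence[float]) -> ClusterSelection:
    """Pick the basis-function count from the within-cluster SS decay curve.

    ``within_ss[i]`` is WS for i+1 clusters. The decay exponent eps of
    WS_j = WS_1 * j^(-eps) is fitted by least squares on the log-log scale
    with the intercept anchored at log WS_1. The selected count is the
    smallest j >= 2 whose observed WS_j lies at or below the fitted curve;
    a near-flat decay (eps < 0.05) selects 1 (no cluster structure).
    Non-positive WS values are excluded from the fit.
    """
    ws = np.asarray(within_ss, dtype=float)
    if ws.size < 3:
        raise ValueError("need WS values for at least 3 cluster counts")
    if ws[0] <= 0:
        raise ValueError("WS_1 must be > 0")
    j = np.arange(1, ws.size + 1)
    usable = ws > 0
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable (positive) WS values")
    log_j = np.log(j[usable])
    log_ratio = np.log(ws[usable]) - np.log(ws[0])
    denom = float(log_j @ log_j)
    eps = -float(log_j @ log_ratio) / denom if denom > 0 else 0.0
    eps = max(eps, 0.0)

    if eps < FLAT_DECAY_EPS:
        selected = 1
    else:
        fitted = ws[0] * j.astype(float) ** (-eps)
        below = np.flatnonzero((ws <= fitted * (1 + 1e-12)) & (j >= 2) & usable)
        selected = int(j[below[0]]) if below.size else 1
    return ClusterSelection(
        cluster_counts=tuple(int(v) for v in j),
        within_ss=tuple(float(v) for v in ws),
        decay_exponent=eps,
        selected=selected,
    )


def scan_cluster_counts(
    points: np.ndarray, s_max: int | None = None, seed: int | None = None
) -> ClusterSelection:
    """Run K-means for j = 1..S_max and select the count from the decay curve."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if s_max is None:
        s_max = min(10, n - 1)
    ws = [kmeans_within_ss(points, j, seed=seed) for j in range(1, s_max + 1)]
    return select_cluster_count(ws)


# ---------------------------------------------------------------------------
# stochastic training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainResult:
    model: RBFNetwork
    training_rmse: float  # on the normalized response scale
    iterations: int
    seed: int | None
    redraws: int = 0


def _trial_rng(seed: int | None, trial: int) -> np.random.Generator:
    # substream per trial: results for trial t do not depend on the total
    # number of trials, so best-of-T is nested in best-of-T' for T < T'
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(trial,)))


def _single_centroid_sigma(n_dims: int) -> float:
    # no pairwise distance exists for S = 1; use the unit-hypercube diameter
    return float(np.sqrt(n_dims) / np.sqrt(2.0))


def train_rbf(
    g: np.ndarray,
    y: np.ndarray,
    s: int,
    trials: int = 10_000,
    seed: int | None = None,
    sigma_override: float | None = None,
) -> TrainResult:
    """Best-of-``trials`` stochastic RBF fit on normalized data.

    Each trial draws ``s`` centroids uniformly in [0, 1]^n, computes the
    shared sigma, solves the pseudo-inverse system for the weights and scores
    the training RMSE; the lowest-RMSE model wins. Reproducible for a fixed
    seed, and trial t's centroid draw is independent of ``trials``.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    y = np.asarray(y, dtype=float)
    n, n_dims = g.shape
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if s < 1:
        raise ValueError("need at least one centroid")
    if n < 2:
        raise ValueError("need at least 2 training rows")
    if y.size != n:
        raise ValueError("g and y must have the same number of rows")

    best: tuple[float, RBFNetwork] | None = None
    redraws = 0
    for t in range(trials):
        rng = _trial_rng(seed, t)
        for _ in range(MAX_CENTROID_REDRAWS + 1):
            centroids = rng.uniform(0.0, 1.0, size=(s, n_dims))
            try:
                if sigma_override is not None:
                    sigma = float(sigma_override)
                elif s == 1:
                    sigma = _single_centroid_sigma(n_dims)
                else:
                    sigma = compute_sigma(centroids)
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("degenerate centroid draws exceeded the redraw cap")
        theta = design_matrix(g, centroids, sigma)
        weights, bias = solve_weights(theta, y)
        score = rmse(theta @ np.concatenate([weights, [bias]]), y)
        if best is None or score < best[0]:
            best = (score, RBFNetwork(centroids=centroids, sigma=sigma,
                                      weights=weights, bias=bias))
    assert best is not None
    return TrainResult(
        model=best[1], training_rmse=best[0], iterations=trials, seed=seed,
        redraws=redraws,
    )
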