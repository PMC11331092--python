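"""Unit exclusion, zero-run imputation, and z-score/PCA reduction.

The preprocessing chain mirrors the study's pipeline: units silent for a
contiguous 50-trial block are excluded; remaining contiguous zero runs
are imputed from the five nearest-neighbor trials across the population;
each unit is z-scored; PCA retains 95% of the variance; and (for the
mixture-model path) each retained dimension is z-scored again.  In
cross-validated analyses all transform parameters are estimated on
training trials only and applied unchanged to test trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer

SD_FLOOR = 1e-8


def zero_runs(x: np.ndarray):
    """(start, length) of every maximal run of zeros in a 1-D array."""
    x = np.asarray(x)
    iszero = np.concatenate([[0], (x == 0).astype(int), [0]])
    diff = np.diff(iszero)
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    return list(zip(starts, ends - starts))


def exclude_dead_units(epoch_or_matrix, block: int = 50) -> np.ndarray:
    """Boolean keep-mask over units.

    A unit is excluded when its per-trial total count (summed over the
    epoch's bins) is zero on ``block`` or more consecutive trials, in the
    session's trial order.
    """
    if block <= 0:
        raise ValueError("block must be positive")
    matrix = epoch_or_matrix.summed() if hasattr(epoch_or_matrix, "summed") else \
        np.asarray(epoch_or_matrix)
    n_units = matrix.shape[1]
    keep = np.ones(n_units, dtype=bool)
    for j in range(n_units):
        if any(length >= block for _, length in zero_runs(matrix[:, j])):
            keep[j] = False
    return keep


def impute_zero_runs(matrix: np.ndarray, k: int = 5):
    """Replace contiguous zero runs by k-nearest-neighbor trial means.

    Cells inside a zero run are masked and filled with the mean of the
    unit's values on the k nearest-neighbor trials, neighbors measured by
    population-vector (nan-aware Euclidean) distance over the other
    units.  Returns ``(imputed, log)`` where ``log`` lists
    ``(unit, run_start, run_length)`` for every modified run.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k >= matrix.shape[0]:
        raise ValueError("k must be smaller than the trial count")
    masked = matrix.copy()
    log = []
    for j in range(matrix.shape[1]):
        for start, length in zero_runs(matrix[:, j]):
            masked[start : start + length, j] = np.nan
            log.append((j, int(start), int(length)))
    if not log:
        return matrix.copy(), log
    imputed = KNNImputer(n_neighbors=k).fit_transform(masked)
    return imputed, log


@dataclass
class PreprocessPipeline:
    """Fitted transform parameters (train-set statistics only)."""

    unit_mean: np.ndarray
    unit_sd: np.ndarray
    components: np.ndarray  # (n_retained, units)
    pca_mean: np.ndarray
    post_mean: np.ndarray | None
    post_sd: np.ndarray | None
    n_retained: int
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[1] != self.unit_mean.size:
            raise ValueError(
                f"expected {self.unit_mean.size} units, got {matrix.shape[1]}"
            )
        z = (matrix - self.unit_mean) / self.unit_sd
        red = (z - self.pca_mean) @ self.components.T
        if self.post_mean is not None:
            red = (red - self.post_mean) / self.post_sd
        return red


def fit_zscore_pca(matrix: np.ndarray, variance: float = 0.95,
                   train_mask=None, second_zscore: bool = False,
                   max_dims: int | None = None) -> PreprocessPipeline:
    """Fit per-unit z-score -> PCA (retaining ``variance``) [-> z-score].

    The second z-score is used on the mixture-model path (each retained
    dimension standardized, matching the model's uniform prior variance).
    ``train_mask`` restricts parameter estimation to training trials.
    """
    if not 0 < variance <= 1:
        raise ValueError("variance must lie in (0, 1]")
    matrix = np.asarray(matrix, dtype=float)
    train = matrix if train_mask is None else matrix[np.asarray(train_mask, dtype=bool)]
    if train.shape[0] < 2:
        raise ValueError("need at least two training trials")
    mean = train.mean(axis=0)
    sd = np.maximum(train.std(axis=0), SD_FLOOR)
    z = (train - mean) / sd
    pca = PCA(n_components=min(z.shape)).fit(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance - 1e-12) + 1)
    if max_dims is not None:
        n_keep = min(n_keep, max_dims)
    components = pca.components_[:n_keep]
    red = (z - pca.mean_) @ components.T
    post_mean = post_sd = None
    if second_zscore:
        post_mean = red.mean(axis=0)
        post_sd = np.maximum(red.std(axis=0), SD_FLOOR)
    return PreprocessPipeline(
        unit_mean=mean, unit_sd=sd, components=components, pca_mean=pca.mean_,
        post_mean=post_mean, post_sd=post_sd, n_retained=n_keep,
        explained_variance_ratio=pca.explained_variance_ratio_[:n_keep],
    )


def apply_pipeline(pipeline: PreprocessPipeline, matrix: np.ndarray) -> np.ndarray:
    """Apply a fitted pipeline (deterministic)."""
    return pipeline.transform(matrix)


class SpikePreprocessor:
    """sklearn-style transformer bundling the full preprocessing chain.

    fit(X) on a (trials, units) count matrix applies dead-unit exclusion,
    zero-run imputation, z-score, PCA to ``variance``, and optionally a
    second z-score; transform(X) maps new trials of the same units into
    the retained space using training statistics only.
    """

    def __init__(self, variance=0.95, block=50, knn_k=5, second_zscore=False,
                 exclude=True, impute=True, max_dims=None):
        self.variance = variance
        self.block = block
        self.knn_k = knn_k
        self.second_zscore = second_zscore
        self.exclude = exclude
        self.impute = impute
        self.max_dims = max_dims

    def get_params(self, deep=True):
        return {"variance": self.variance, "block": self.block, "knn_k": self.knn_k,
                "second_zscore": self.second_zscore, "exclude": self.exclude,
                "impute": self.impute, "max_dims": self.max_dims}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, train_mask=None):
        X = np.asarray(X, dtype=float)
        self.keep_mask_ = (
            exclude_dead_units(X, self.block) if self.exclude
            else np.ones(X.shape[1], dtype=bool)
        )
        kept = X[:, self.keep_mask_]
        if self.impute:
            kept, self.imputation_log_ = impute_zero_runs(kept, self.knn_k)
        else:
            self.imputation_log_ = []
        self.pipeline_ = fit_zscore_pca(
            kept, self.variance, train_mask=train_mask,
            second_zscore=self.second_zscore, max_dims=self.max_dims,
        )
        self.n_retained_ = self.pipeline_.n_retained
        return self

    def transform(self, X):
        if not hasattr(self, "pipeline_"):
            raise RuntimeError("not fitted")
        X = np.asarray(X, dtype=float)[:, self.keep_mask_]
        if self.impute:
            X, _ = impute_zero_runs(X, min(self.knn_k, max(1, X.shape[0] - 1)))
        return self.pipeline_.transform(X)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).transform(X)
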