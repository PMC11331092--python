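"""Cross-validated projection, distance, and embedding analyses.

These analyses replicate the mixture model's conclusions with
cross-validated, decoder-style techniques:

* **Projection index** — for a held-out trial r and two prototypes
  rbar_A, rbar_B, x = (rbar_A - rbar_B) . (r - rbar_B) / ||rbar_A - rbar_B||^2,
  so x = 0 at rbar_B (nominal) and x = 1 at rbar_A (the hypothesized
  error representation); the anchored form is the default, the
  unanchored variant ((rbar_A - rbar_B) . r / ||.||^2) is available.
* **Leave-one-out analysis** — the encoder is refit on likely-correct
  trials with one held out, prototypes are built per trial, and the mean
  x over likely-swap trials is compared with the mean over held-out
  likely-correct trials.
* **Cross-validated squared distance** — for trial pairs drawn from two
  condition groups, d12 = (t1 - t2) . (mean group A others - mean group B
  others); the two factors come from disjoint trials so the estimate of
  the squared separation is unbiased (it may be negative by sampling).
* **Classical MDS** — Torgerson embedding of the 3x3 distance matrix;
  three points embed into the plane without distortion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circ_dist
from .encoders import fit_encoder_ridge, substitute_condition
from .splines import SplineBasisSpec


def projection_index(r, proto_a, proto_b, anchored: bool = True):
    """Normalized position of ``r`` along the prototype axis.

    0 at proto_b, 1 at proto_a (anchored form); invariant to components
    of ``r`` orthogonal to the axis.  ``r`` may be a vector or a matrix of
    row vectors.
    """
    proto_a = np.asarray(proto_a, dtype=float)
    proto_b = np.asarray(proto_b, dtype=float)
    axis = proto_a - proto_b
    norm2 = float(axis @ axis)
    if norm2 <= 1e-20:
        raise ValueError("prototypes coincide; projection axis is degenerate")
    r = np.asarray(r, dtype=float)
    ref = proto_b if anchored else 0.0
    return (r - ref) @ axis / norm2


@dataclass
class ProjectionSummary:
    """Per-class projection indices and their difference with bootstrap CI."""

    x_correct: np.ndarray
    x_swap: np.ndarray
    mean_correct: float
    mean_swap: float
    difference: float
    ci_low: float
    ci_high: float
    hypothesis_pair: tuple = ("misbound", "nominal")
    window_time: float | None = None


def _classify_trials(behav: pd.DataFrame, p_correct_min: float, p_swap_min: float):
    correct = behav["p_correct_post"].to_numpy() > p_correct_min
    swap = behav["p_swap_post"].to_numpy() > p_swap_min
    return correct, swap


def _bootstrap_diff(x_correct, x_swap, rng, n_boot=1000):
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        c = rng.choice(x_correct, size=len(x_correct), replace=True)
        s = rng.choice(x_swap, size=len(x_swap), replace=True)
        diffs[b] = s.mean() - c.mean()
    return float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5))


def _prototype_pair(encoder, row, pair, anchored_report=None):
    from .encoders import make_prototype

    alt, nom = pair
    pa = make_prototype(encoder, row, alt, c_report=row.c_report)
    pb = make_prototype(encoder, row, nom, c_report=row.c_report)
    return pa.mean, pb.mean


def loo_projection_analysis(
    activity: np.ndarray,
    trials: pd.DataFrame,
    behav: pd.DataFrame,
    epoch: str = "delay1",
    hypothesis_pair: tuple = ("misbound", "nominal"),
    *,
    p_correct_min: float = 0.3,
    p_swap_min: float = 0.3,
    color_separation_min: float = np.pi / 4,
    alpha: float = 1.0,
    basis: SplineBasisSpec | None = None,
    preprocessor=None,
    n_boot: int = 1000,
    seed: int = 0,
    anchored: bool = True,
) -> ProjectionSummary:
    """Leave-one-out projection analysis of likely-swap vs likely-correct trials.

    The encoder is refit once per held-out likely-correct trial, on the
    remaining likely-correct trials; trial-specific prototypes (first
    element of ``hypothesis_pair`` maps to x = 1, second to x = 0) score
    the held-out trial and every likely-swap trial.  If ``preprocessor``
    (an unfitted SpikePreprocessor) is supplied it too is refit within
    each fold, so no held-out statistic leaks into any transform.
    """
    basis = basis or SplineBasisSpec()
    activity = np.asarray(activity, dtype=float)
    trials = trials.reset_index(drop=True)
    behav = behav.reset_index(drop=True)
    correct, swap = _classify_trials(behav, p_correct_min, p_swap_min)
    sep = np.abs(circ_dist(trials["u"].to_numpy(dtype=float),
                           trials["l"].to_numpy(dtype=float)))
    wide = sep >= color_separation_min
    correct &= wide
    swap &= wide
    c_idx = np.where(correct)[0]
    s_idx = np.where(swap)[0]
    if len(c_idx) < 10:
        raise ValueError(f"need >= 10 likely-correct trials, have {len(c_idx)}")
    if len(s_idx) == 0:
        warnings.warn("no likely-swap trials; returning correct-only result")

    x_correct = np.empty(len(c_idx))
    x_swap_folds = np.zeros((len(c_idx), len(s_idx)))
    for fi, held in enumerate(c_idx):
        train = c_idx[c_idx != held]
        if preprocessor is not None:
            prep = type(preprocessor)(**preprocessor.get_params())
            act = prep.fit(activity[train]).transform(activity)
        else:
            act = activity
        enc = fit_encoder_ridge(act[train], trials.iloc[train], epoch=epoch,
                                alpha=alpha, basis=basis)
        row = trials.iloc[held]
        pa, pb = _prototype_pair(enc, row, hypothesis_pair)
        x_correct[fi] = projection_index(act[held], pa, pb, anchored=anchored)
        for sj, s in enumerate(s_idx):
            srow = trials.iloc[s]
            pa, pb = _prototype_pair(enc, srow, hypothesis_pair)
            x_swap_folds[fi, sj] = projection_index(act[s], pa, pb, anchored=anchored)
    x_swap = x_swap_folds.mean(axis=0) if len(s_idx) else np.array([])

    mean_c = float(x_correct.mean())
    mean_s = float(x_swap.mean()) if len(x_swap) else np.nan
    diff = mean_s - mean_c if len(x_swap) else np.nan
    if len(x_swap):
        lo, hi = _bootstrap_diff(x_correct, x_swap, np.random.default_rng(seed), n_boot)
    else:
        lo = hi = np.nan
    return ProjectionSummary(
        x_correct=x_correct, x_swap=x_swap, mean_correct=mean_c, mean_swap=mean_s,
        difference=diff, ci_low=lo, ci_high=hi, hypothesis_pair=hypothesis_pair,
    )


def window_starts(t_min: float, t_max: float, width: float, step: float) -> np.ndarray:
    """Left edges of sliding windows covering [t_min, t_max]."""
    n = int(np.floor((t_max - t_min - width) / step + 1e-9)) + 1
    if n < 1:
        raise ValueError("window does not fit in the recorded range")
    return t_min + step * np.arange(n)


def sliding_window_timecourse(
    epoch, trials, behav, hypothesis_pair=("misselected_colors", "nominal"),
    *, width: float = 0.5, step: float = 0.05, model_epoch: str = "delay2",
    **kwargs,
) -> list[ProjectionSummary]:
    """Projection analysis in sliding windows over a time-binned epoch.

    ``epoch`` is a NeuralEpoch whose bins tile the analysis range; counts
    are summed over the bins falling inside each window (bins must align
    with the window grid).
    """
    edges = epoch.bin_edges
    starts = window_starts(edges[0], edges[-1], width, step)
    out = []
    for w0 in starts:
        inside = (edges[:-1] >= w0 - 1e-9) & (edges[1:] <= w0 + width + 1e-9)
        if not inside.any():
            raise ValueError(f"window [{w0}, {w0 + width}) covers no bins")
        mat = epoch.counts[:, :, inside].sum(axis=2).astype(float)
        summary = loo_projection_analysis(
            mat, trials, behav, epoch=model_epoch,
            hypothesis_pair=hypothesis_pair, **kwargs,
        )
        summary.window_time = float(w0 + width / 2)
        out.append(summary)
    return out


# ---------------------------------------------------------------------------
# cross-validated distances and the 3-point geometry


def _condition_keys(trials: pd.DataFrame, hypothesis: str, n_color_bins: int = 8):
    """Group key per trial: the trial's condition mapped through the
    hypothesis relabeling, colors quantized to an ``n_color_bins`` circular
    partition, cue kept exact."""
    u = trials["u"].to_numpy(dtype=float)
    l = trials["l"].to_numpy(dtype=float)
    c = trials["c"].to_numpy()
    u2 = np.empty_like(u)
    l2 = np.empty_like(l)
    c2 = np.empty_like(c)
    for i in range(len(u)):
        u2[i], l2[i], c2[i] = substitute_condition(u[i], l[i], int(c[i]), hypothesis)
    width = 2 * np.pi / n_color_bins
    bu = (np.floor(u2 / width) % n_color_bins).astype(int)
    bl = (np.floor(l2 / width) % n_color_bins).astype(int)
    return [(int(a), int(b), int(cc)) for a, b, cc in zip(bu, bl, c2)]


def cv_squared_distance(
    activity: np.ndarray,
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame | None = None,
    *,
    idx_a=None,
    idx_b=None,
    hypothesis_a: str = "nominal",
    hypothesis_b: str = "nominal",
    n_color_bins: int = 8,
):
    """All-pairs cross-validated squared-distance estimates between two
    condition groups.

    ``idx_a`` / ``idx_b`` are row indices into ``activity`` for the trials
    of each group (defaulting to all rows of ``trials_a`` / ``trials_b``).
    Trials enter a pair when their hypothesis-mapped conditions share a
    group key (cue exact, each color within one bin of the circular
    partition).  Returns ``(estimates, mean, se)``; estimates may be
    negative by sampling — their expectation is the squared Euclidean
    separation of the condition means.
    """
    activity = np.asarray(activity, dtype=float)
    if trials_b is None:
        trials_b = trials_a
    idx_a = np.arange(len(trials_a)) if idx_a is None else np.asarray(idx_a)
    idx_b = np.arange(len(trials_b)) if idx_b is None else np.asarray(idx_b)
    keys_a = _condition_keys(trials_a, hypothesis_a, n_color_bins)
    keys_b = _condition_keys(trials_b, hypothesis_b, n_color_bins)
    groups_a: dict = {}
    for row, key in zip(idx_a, keys_a):
        groups_a.setdefault(key, []).append(row)
    groups_b: dict = {}
    for row, key in zip(idx_b, keys_b):
        groups_b.setdefault(key, []).append(row)

    estimates = []
    for key in sorted(set(groups_a) & set(groups_b)):
        rows_a = np.asarray(groups_a[key])
        rows_b = np.asarray(groups_b[key])
        for t1 in rows_a:
            for t2 in rows_b:
                if t1 == t2:
                    continue
                rest_a = rows_a[(rows_a != t1) & (rows_a != t2)]
                rest_b = rows_b[(rows_b != t1) & (rows_b != t2)]
                if len(rest_a) == 0 or len(rest_b) == 0:
                    continue
                v_a = activity[t1] - activity[t2]
                v_b = activity[rest_a].mean(axis=0) - activity[rest_b].mean(axis=0)
                estimates.append(float(v_a @ v_b))
    estimates = np.asarray(estimates)
    if len(estimates) == 0:
        return estimates, np.nan, np.nan
    mean = float(estimates.mean())
    se = float(estimates.std(ddof=1) / np.sqrt(len(estimates))) if len(estimates) > 1 else np.nan
    return estimates, mean, se


RETRO_TRIPLET = ("nominal", "misselected_colors", "misinterpreted_cue")
PRO_TRIPLET = ("nominal", "misselected_colors", "misinterpreted_cue")


@dataclass
class CVDistanceMatrix:
    """3x3 symmetric matrix of signed squared-distance estimates."""

    labels: tuple
    matrix: np.ndarray          # signed mean estimates, zero diagonal
    se: np.ndarray
    pair_counts: np.ndarray
    incomplete: bool = False
    session_id: str = "s0"

    def rooted(self) -> np.ndarray:
        """Distances for visualization/MDS: sqrt(max(cell, 0))."""
        return np.sqrt(np.clip(self.matrix, 0.0, None))


def session_distance_matrix(
    activity, trials, behav, *, triplet=RETRO_TRIPLET,
    p_correct_min: float = 0.3, n_color_bins: int = 8, session_id: str = "s0",
) -> CVDistanceMatrix:
    """Cross-validated distance matrix between three hypothesized
    representations, estimated from likely-correct trials only."""
    trials = trials.reset_index(drop=True)
    behav = behav.reset_index(drop=True)
    keep = np.where(behav["p_correct_post"].to_numpy() > p_correct_min)[0]
    mat = np.zeros((3, 3))
    se = np.zeros((3, 3))
    counts = np.zeros((3, 3), dtype=int)
    incomplete = False
    for i in range(3):
        for j in range(i + 1, 3):
            est, mean, _se = cv_squared_distance(
                activity, trials, idx_a=keep, idx_b=keep,
                hypothesis_a=triplet[i], hypothesis_b=triplet[j],
                n_color_bins=n_color_bins,
            )
            if len(est) == 0:
                incomplete = True
                mean, _se = np.nan, np.nan
            mat[i, j] = mat[j, i] = mean
            se[i, j] = se[j, i] = _se
            counts[i, j] = counts[j, i] = len(est)
    return CVDistanceMatrix(
        labels=tuple(triplet), matrix=mat, se=se, pair_counts=counts,
        incomplete=incomplete, session_id=session_id,
    )


def average_distance_matrices(matrices: list[CVDistanceMatrix],
                              weighting: str = "simple") -> CVDistanceMatrix:
    """Average session matrices (simple mean by default; ``weighting='pairs'``
    weights each session cell by its pair count)."""
    if not matrices:
        raise ValueError("need at least one matrix")
    stack = np.stack([m.matrix for m in matrices])
    counts = np.stack([m.pair_counts for m in matrices])
    if weighting == "pairs":
        w = counts / np.maximum(counts.sum(axis=0, keepdims=True), 1)
        avg = np.nansum(stack * w, axis=0)
    else:
        avg = np.nanmean(stack, axis=0)
    np.fill_diagonal(avg, 0.0)
    return CVDistanceMatrix(
        labels=matrices[0].labels, matrix=avg,
        se=np.nanmean(np.stack([m.se for m in matrices]), axis=0),
        pair_counts=counts.sum(axis=0),
        incomplete=any(m.incomplete for m in matrices),
        session_id="average",
    )


def mds_embed(matrix) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a 3-point distance matrix.

    ``matrix`` may be a CVDistanceMatrix (cells are signed squared
    estimates; negatives are floored at zero before the root) or a plain
    array of distances.  Three points with metric distances are embedded
    in the plane exactly.
    """
    if isinstance(matrix, CVDistanceMatrix):
        dist = matrix.rooted()
    else:
        dist = np.asarray(matrix, dtype=float)
    n = dist.shape[0]
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n >= 3 and vals[0] > 0 and vals.min() < -1e-6 * max(vals[0], 1.0):
        warnings.warn("distance matrix violates the triangle inequality after "
                      "flooring; embedding carries distortion")
    take = min(2, n)
    coords = vecs[:, :take] * np.sqrt(np.clip(vals[:take], 0.0, None))
    if take < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - take)))
    return coords
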