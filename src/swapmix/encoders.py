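"""Linear population encoding models on periodic spline features.

Delay 1 (before the cue in the retrospective task) models the population
response as a linear function of both colors,

    r(u, l) = W_u f(u) + W_l f(l) + eta,    eta ~ N(0, diag(sigma^2)),

where f is the K-dimensional periodic spline basis.  Delay 2 adds the cue
c (1 = upper cued) with role-specific color weights and cue-specific
intercepts:

    c = 1:  r = W_ut f(u) + W_ld f(l) + b_1 + eta
    c = 0:  r = W_lt f(l) + W_ud f(u) + b_0 + eta

(W_ut: upper color as target, W_ud: upper as distractor, etc.; the
intercept subscripts simply label the two cues).  Noise is diagonal — no
full covariance is fit.  Hypothesis prototypes are model means evaluated
at counterfactual stimulus/cue assignments (misbound, misselected colors,
misinterpreted cue, reported guess).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineBasisSpec, spline_basis

DELAY1_HYPOTHESES = ("nominal", "misbound", "reported_guess")
DELAY2_HYPOTHESES = ("nominal", "misselected_colors", "misinterpreted_cue", "reported_guess")


@dataclass
class Delay1Encoder:
    """Two-color linear encoder: r(u, l) = W_u f(u) + W_l f(l)."""

    W_u: np.ndarray  # (dims, K)
    W_l: np.ndarray
    sigma: np.ndarray  # (dims,)
    basis: SplineBasisSpec = field(default_factory=SplineBasisSpec)

    @property
    def n_dims(self) -> int:
        return self.W_u.shape[0]

    @property
    def theta(self) -> np.ndarray:
        """Stacked coefficient matrix (dims, 2K): [W_u | W_l]."""
        return np.concatenate([self.W_u, self.W_l], axis=1)

    @classmethod
    def from_theta(cls, theta, sigma, basis):
        K = basis.n_knots
        return cls(theta[:, :K], theta[:, K : 2 * K], np.asarray(sigma), basis)


@dataclass
class Delay2Encoder:
    """Cue-dependent encoder with role-specific color weights."""

    W_ut: np.ndarray  # (dims, K) upper color as target
    W_ud: np.ndarray  # upper as distractor
    W_lt: np.ndarray  # lower as target
    W_ld: np.ndarray  # lower as distractor
    b_0: np.ndarray  # (dims,) intercept, cue = 0 (lower cued)
    b_1: np.ndarray  # intercept, cue = 1 (upper cued)
    sigma: np.ndarray
    basis: SplineBasisSpec = field(default_factory=SplineBasisSpec)

    @property
    def n_dims(self) -> int:
        return self.W_ut.shape[0]

    @property
    def theta(self) -> np.ndarray:
        """(dims, 4K + 2): [W_ut | W_ud | W_lt | W_ld | b_0 | b_1]."""
        return np.concatenate(
            [self.W_ut, self.W_ud, self.W_lt, self.W_ld,
             self.b_0[:, None], self.b_1[:, None]], axis=1
        )

    @classmethod
    def from_theta(cls, theta, sigma, basis):
        K = basis.n_knots
        return cls(
            theta[:, :K], theta[:, K : 2 * K], theta[:, 2 * K : 3 * K],
            theta[:, 3 * K : 4 * K], theta[:, 4 * K], theta[:, 4 * K + 1],
            np.asarray(sigma), basis,
        )


@dataclass
class HypothesisPrototype:
    """A model-mean population vector under a hypothesized assignment."""

    hypothesis: str
    mean: np.ndarray
    condition: tuple  # effective (u, l, c) fed to the encoder


def delay1_design(u, l, basis: SplineBasisSpec) -> np.ndarray:
    """Design matrix (n, 2K) so that mean = design @ encoder.theta.T."""
    return np.concatenate([spline_basis(u, basis), spline_basis(l, basis)], axis=-1)


def delay2_design(u, l, c, basis: SplineBasisSpec) -> np.ndarray:
    """Design matrix (n, 4K + 2) for the cue-dependent model.

    Missing colors (NaN, single-stimulus trials) contribute zero columns.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    l = np.atleast_1d(np.asarray(l, dtype=float))
    c = np.atleast_1d(np.asarray(c))
    if not np.isin(c[~pd.isna(c)], [0, 1]).all():
        raise ValueError("cue must be binary")
    K = basis.n_knots
    n = len(u)
    fu = np.where(np.isnan(u)[:, None], 0.0, spline_basis(np.nan_to_num(u), basis))
    fl = np.where(np.isnan(l)[:, None], 0.0, spline_basis(np.nan_to_num(l), basis))
    X = np.zeros((n, 4 * K + 2))
    c1 = c == 1
    X[c1, :K] = fu[c1]                   # W_ut f(u)
    X[c1, 3 * K : 4 * K] = fl[c1]        # W_ld f(l)
    X[c1, 4 * K + 1] = 1.0               # b_1
    c0 = ~c1
    X[c0, K : 2 * K] = fu[c0]            # W_ud f(u)
    X[c0, 2 * K : 3 * K] = fl[c0]        # W_lt f(l)
    X[c0, 4 * K] = 1.0                   # b_0
    return X


def predict_delay1(encoder: Delay1Encoder, u, l) -> np.ndarray:
    """Mean population response r(u, l); noise excluded."""
    X = delay1_design(np.atleast_1d(u), np.atleast_1d(l), encoder.basis)
    out = X @ encoder.theta.T
    return out[0] if np.isscalar(u) else out


def predict_delay2(encoder: Delay2Encoder, u, l, c) -> np.ndarray:
    """Mean population response r(u, l, c); noise excluded."""
    X = delay2_design(u, l, c, encoder.basis)
    out = X @ encoder.theta.T
    return out[0] if np.isscalar(u) or (np.isscalar(c) and np.ndim(u) == 0) else out


def substitute_condition(u, l, c, hypothesis: str, c_report=None):
    """Map a trial's veridical (u, l, c) to the condition whose nominal
    representation realizes ``hypothesis``.

    nominal: identity.  misbound / misselected_colors: colors swap
    locations / roles, (l, u, c).  misinterpreted_cue: (u, l, 1 - c).
    reported_guess: the reported color replaces the target-role color,
    the distractor is unchanged.
    """
    if hypothesis in ("nominal",):
        return u, l, c
    if hypothesis in ("misbound", "misselected_colors"):
        return l, u, c
    if hypothesis == "misinterpreted_cue":
        return u, l, 1 - c
    if hypothesis == "reported_guess":
        if c_report is None:
            raise ValueError("reported_guess prototype requires c_report")
        return (c_report, l, c) if c == 1 else (u, c_report, c)
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def make_prototype(encoder, trial, hypothesis: str, c_report=None) -> HypothesisPrototype:
    """Model-mean prototype for ``trial`` under ``hypothesis``.

    ``trial`` supplies u, l, c (a TrialRecord, a mapping, or a namedtuple
    row); ``c_report`` defaults to the trial's own report.
    """
    u, l, c = (getattr(trial, "u", None), getattr(trial, "l", None), getattr(trial, "c", None))
    if u is None and isinstance(trial, dict):
        u, l, c = trial["u"], trial["l"], trial["c"]
    if c_report is None:
        c_report = getattr(trial, "c_report", None)
    u2, l2, c2 = substitute_condition(u, l, int(c), hypothesis, c_report)
    if isinstance(encoder, Delay1Encoder):
        if hypothesis == "misinterpreted_cue":
            raise ValueError("misinterpreted_cue is a delay-2 hypothesis")
        mean = predict_delay1(encoder, np.array([u2]), np.array([l2]))[0]
    else:
        if hypothesis == "misbound":
            hypothesis = "misselected_colors"
        mean = predict_delay2(encoder, np.array([u2]), np.array([l2]), np.array([c2]))[0]
    return HypothesisPrototype(hypothesis=hypothesis, mean=mean, condition=(u2, l2, c2))


def _design_for_epoch(trials: pd.DataFrame, epoch: str, basis: SplineBasisSpec):
    u = trials["u"].to_numpy(dtype=float)
    l = trials["l"].to_numpy(dtype=float)
    if epoch == "delay1":
        if np.isnan(u).any() or np.isnan(l).any():
            raise ValueError("delay-1 design requires both colors on every trial")
        return delay1_design(u, l, basis)
    elif epoch == "delay2":
        return delay2_design(u, l, trials["c"].to_numpy(), basis)
    raise ValueError(f"unknown epoch {epoch!r}")


def fit_encoder_ridge(activity: np.ndarray, trials: pd.DataFrame, epoch: str = "delay1",
                      alpha: float = 1.0, trial_mask=None,
                      basis: SplineBasisSpec | None = None):
    """Per-dimension ridge fit of the epoch's spline design.

    Returns a Delay1Encoder or Delay2Encoder with residual SDs stored as
    sigma.  ``trial_mask`` restricts fitting to a subset (e.g. likely
    correct trials); degenerate designs (all trials one cue) trigger a
    rank warning and proceed via the regularized solve.
    """
    basis = basis or SplineBasisSpec()
    activity = np.asarray(activity, dtype=float)
    if trial_mask is not None:
        trial_mask = np.asarray(trial_mask, dtype=bool)
        activity = activity[trial_mask]
        trials = trials.loc[trial_mask] if hasattr(trials, "loc") else trials[trial_mask]
    X = _design_for_epoch(trials, epoch, basis)
    n, p = X.shape
    if n <= p:
        warnings.warn(f"only {n} trials for a {p}-column design; fit may be weak")
    # the periodic basis sums to 1, so mild collinearity with intercepts is
    # expected; warn only for a degenerate condition set (e.g. a single cue)
    if epoch == "delay2" and trials["c"].nunique() < 2:
        warnings.warn("all trials share one cue value; the other cue's "
                      "weights are determined by the ridge penalty alone")
    theta = np.linalg.solve(X.T @ X + alpha * np.eye(p), X.T @ activity).T
    resid = activity - X @ theta.T
    sigma = np.maximum(resid.std(axis=0, ddof=min(p, n - 1)), 1e-12)
    if epoch == "delay1":
        return Delay1Encoder.from_theta(theta, sigma, basis)
    return Delay2Encoder.from_theta(theta, sigma, basis)


class SplineEncoderRegression:
    """sklearn-style wrapper: trials in, population activity out.

    Parameters: epoch ("delay1"/"delay2"), alpha (ridge penalty on the
    z-scored feature scale), n_knots, order.  After ``fit(trials,
    activity)`` the fitted model lives in ``encoder_`` and ``predict``
    returns model means for new trials.
    """

    def __init__(self, epoch="delay1", alpha=1.0, n_knots=5, order=1):
        self.epoch = epoch
        self.alpha = alpha
        self.n_knots = n_knots
        self.order = order

    def get_params(self, deep=True):
        return {"epoch": self.epoch, "alpha": self.alpha,
                "n_knots": self.n_knots, "order": self.order}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame, activity: np.ndarray, trial_mask=None):
        basis = SplineBasisSpec(self.n_knots, self.order)
        self.encoder_ = fit_encoder_ridge(
            activity, trials, epoch=self.epoch, alpha=self.alpha,
            trial_mask=trial_mask, basis=basis,
        )
        return self

    def predict(self, trials: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("not fitted")
        X = _design_for_epoch(trials, self.epoch, self.encoder_.basis)
        return X @ self.encoder_.theta.T

    def score(self, trials: pd.DataFrame, activity: np.ndarray) -> float:
        """Coefficient of determination pooled over dimensions."""
        pred = self.predict(trials)
        activity = np.asarray(activity, dtype=float)
        ss_res = np.sum((activity - pred) ** 2)
        ss_tot = np.sum((activity - activity.mean(axis=0)) ** 2)
        return 1.0 - ss_res / ss_tot
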