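"""Bayesian neural mixture model over hypothesized error representations.

For each trial the preprocessed population activity r is modelled as a
mixture of diagonal-Gaussian components centered on encoding-model
prototypes, with weights gated by the trial's *fixed* behavioral
response-type posteriors (p_correct, p_swap, p_guess taken from the
behavioral model, not fit here).  During delay 1:

    P(r | u, l) = p_C             N(r | rbar(u, l),        sigma)
                + p_swap p_misbind  N(r | rbar(l, u),        sigma)
                + p_guess p_resp    N(r | rbar(c_report, l), sigma)

with p_C = p_correct + p_swap (1 - p_misbind) + p_guess (1 - p_resp) the
accumulated probability of the nominal representation.  During delay 2
(cue known) the swap branch splits into a selection error (role-swapped
colors) and a cue-misinterpretation error (flipped cue):

    P(r | u, l, c) = p_C                 N(r | rbar(u, l, c),     sigma)
                   + p_swap p_selection    N(r | rbar(l, u, c),     sigma)
                   + p_swap p_cue          N(r | rbar(u, l, 1 - c), sigma)
                   + p_guess p_resp        N(r | rbar(creport -> t), sigma)

with p_C = p_correct + p_swap (1 - p_selection - p_cue) + p_guess (1 - p_resp).
In the prospective task the same delay-2 likelihood applies with relabeled
semantics (its "selection" slot plays the role of misbinding, its "cue"
slot the role of selection).

Encoder weights, per-dimension noise SDs, and the mixture scalars are fit
*simultaneously* by HMC.  Weights are sampled in design-whitened
coordinates with standard-normal priors (a unit-information ridge on the
natural weights; activity is z-scored after PCA so weights are order
one), noise SDs get half-normal(10) priors, and the mixture
probabilities get uniform priors — flat on
[0, 1] for p_misbind / p_resp, and uniform over the constrained simplex
p_selection + p_cue <= 1 via a stick-breaking reparameterization.  An
optional hierarchical mode shares encoder weights across task types
(retro / pro / single): per-type weights are normal deviations around a
shared mean with per-entry SDs (normal / half-normal hyperpriors on the
whitened scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoders import Delay1Encoder, Delay2Encoder, delay2_design
from .hmc import HMCResult, diag_hessian_inv_mass, find_map, sample_hmc, split_rhat
from .splines import SplineBasisSpec, spline_basis

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureWeights:
    """Error-representation probabilities (one set per session/model)."""

    p_misbind: float | None = None   # delay 1 (or its delay-2-pro analogue)
    p_selection: float | None = None  # delay 2
    p_cue: float | None = None        # delay 2
    p_resp: float = 0.0

    def __post_init__(self):
        for name in ("p_misbind", "p_selection", "p_cue", "p_resp"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_selection is not None and self.p_cue is not None:
            if self.p_selection + self.p_cue > 1 + 1e-9:
                raise ValueError("p_selection + p_cue must not exceed 1")

    def p_C(self, p_correct, p_swap, p_guess):
        """Accumulated nominal-representation probability for a trial."""
        if self.p_selection is not None:
            alt = self.p_selection + (self.p_cue or 0.0)
        else:
            alt = self.p_misbind or 0.0
        return p_correct + p_swap * (1 - alt) + p_guess * (1 - self.p_resp)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def design_whitener(designs: np.ndarray, weights: np.ndarray | None = None,
                    ridge: float = 0.01):
    """Cholesky whitener of the mixture-weighted design Gram.

    G = sum_m mean_t w[t, m] x_{t,m} x_{t,m}^T + ridge I, with w the
    per-trial component weights (the behavioral gates at neutral mixture
    scalars); returns (L, Linv) with L = chol(G).  Fitting weights in the
    whitened coordinates removes the exact collinearity the
    partition-of-unity spline basis induces and matches the likelihood
    curvature the dominant (nominal) component contributes.
    """
    M, n, P = designs.shape
    if weights is None:
        weights = np.full((n, M), 1.0 / M)
    G = ridge * np.eye(P)
    for m in range(M):
        Xw = designs[m] * weights[:, m : m + 1]
        G += Xw.T @ designs[m] / max(n, 1)
    L = np.linalg.cholesky(G)
    return L, np.linalg.inv(L)


def _neutral_gate_weights(behav: np.ndarray, epoch: str) -> np.ndarray:
    """Component gate weights at noncommittal mixture scalars (prior means)."""
    if epoch == "delay1":
        scalars = {"p_misbind": 0.5, "p_resp": 0.5}
    else:
        scalars = {"p_selection": 1.0 / 3, "p_cue": 1.0 / 3, "p_resp": 0.5}
    return _component_log_weights(np.asarray(behav, dtype=float), epoch, scalars)


def _component_designs(trials: pd.DataFrame, epoch: str, basis: SplineBasisSpec):
    """Stacked design matrices, one per mixture component.

    Returns (designs, names): designs has shape (n_components, n, P).
    """
    u = trials["u"].to_numpy(dtype=float)
    l = trials["l"].to_numpy(dtype=float)
    c = trials["c"].to_numpy()
    rep = trials["c_report"].to_numpy(dtype=float)
    # reported color replaces the target-role color
    u_rep = np.where(c == 1, rep, u)
    l_rep = np.where(c == 0, rep, l)
    if epoch == "delay1":
        def d1(a, b):
            fa = np.where(np.isnan(a)[:, None], 0.0, spline_basis(np.nan_to_num(a), basis))
            fb = np.where(np.isnan(b)[:, None], 0.0, spline_basis(np.nan_to_num(b), basis))
            return np.concatenate([fa, fb], axis=1)

        designs = np.stack([d1(u, l), d1(l, u), d1(u_rep, l_rep)])
        names = ["nominal", "misbound", "reported_guess"]
    else:
        designs = np.stack([
            delay2_design(u, l, c, basis),
            delay2_design(l, u, c, basis),
            delay2_design(u, l, 1 - c, basis),
            delay2_design(u_rep, l_rep, c, basis),
        ])
        names = ["nominal", "misselected_colors", "misinterpreted_cue", "reported_guess"]
    return designs, names


def _component_log_weights(behav, epoch, scalars):
    """Per-trial mixture weights (n, M) from behavioral posteriors + scalars.

    behav: (n, 3) columns p_correct, p_swap, p_guess.  scalars: dict with
    p_misbind/p_resp (delay1) or p_selection/p_cue/p_resp (delay2).
    """
    pc, ps, pg = behav[:, 0], behav[:, 1], behav[:, 2]
    pr = scalars["p_resp"]
    if epoch == "delay1":
        pm = scalars["p_misbind"]
        w = np.stack([
            pc + ps * (1 - pm) + pg * (1 - pr), ps * pm, pg * pr,
        ], axis=1)
    else:
        psel, pcue = scalars["p_selection"], scalars["p_cue"]
        w = np.stack([
            pc + ps * (1 - psel - pcue) + pg * (1 - pr),
            ps * psel, ps * pcue, pg * pr,
        ], axis=1)
    return w


def _mixture_loglik_rows(activity, designs, theta, sigma, weights):
    """Row-wise mixture log likelihood.

    activity (n, D); designs (M, n, P); theta (D, P); sigma (D,);
    weights (n, M).  Returns (loglik_rows (n,), gamma (n, M), mu (M, n, D)).
    """
    M = designs.shape[0]
    n, D = activity.shape
    log_comp = np.empty((n, M))
    mus = np.empty((M, n, D))
    const = -0.5 * D * LOG2PI - np.sum(np.log(sigma))
    inv_var = 1.0 / sigma**2
    for m in range(M):
        mu = designs[m] @ theta.T
        mus[m] = mu
        d = activity - mu
        log_comp[:, m] = const - 0.5 * np.sum(d * d * inv_var, axis=1)
    with np.errstate(divide="ignore"):
        a = log_comp + np.log(weights)
    amax = a.max(axis=1, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    lse = amax[:, 0] + np.log(np.sum(np.exp(a - amax), axis=1))
    gamma = np.exp(a - lse[:, None])
    return lse, gamma, mus


def delay1_mixture_loglik(activity_row, trial, behav_probs, encoder: Delay1Encoder,
                          weights: MixtureWeights) -> float:
    """Log likelihood of one delay-1 activity vector under the mixture."""
    trials = pd.DataFrame([{
        "u": trial.u, "l": trial.l, "c": trial.c, "c_report": trial.c_report,
    }])
    designs, _ = _component_designs(trials, "delay1", encoder.basis)
    w = _component_log_weights(
        np.asarray([behav_probs], dtype=float), "delay1",
        {"p_misbind": weights.p_misbind or 0.0, "p_resp": weights.p_resp},
    )
    lse, _, _ = _mixture_loglik_rows(
        np.atleast_2d(activity_row), designs, encoder.theta, encoder.sigma, w
    )
    return float(lse[0])


def delay2_mixture_loglik(activity_row, trial, behav_probs, encoder: Delay2Encoder,
                          weights: MixtureWeights) -> float:
    """Log likelihood of one delay-2 activity vector under the mixture."""
    if (weights.p_selection or 0.0) + (weights.p_cue or 0.0) > 1 + 1e-9:
        raise ValueError("p_selection + p_cue must not exceed 1")
    trials = pd.DataFrame([{
        "u": trial.u, "l": trial.l, "c": trial.c, "c_report": trial.c_report,
    }])
    designs, _ = _component_designs(trials, "delay2", encoder.basis)
    w = _component_log_weights(
        np.asarray([behav_probs], dtype=float), "delay2",
        {"p_selection": weights.p_selection or 0.0, "p_cue": weights.p_cue or 0.0,
         "p_resp": weights.p_resp},
    )
    lse, _, _ = _mixture_loglik_rows(
        np.atleast_2d(activity_row), designs, encoder.theta, encoder.sigma, w
    )
    return float(lse[0])


class _MixtureProblem:
    """Unconstrained log posterior + gradient for one task-type group.

    Layout (non-hierarchical): [vec(theta) (P*D), log sigma (D), scalars]
    where scalars are logits: delay1 (a_misbind, a_resp), delay2
    (a_sel, a_cue, a_resp) with stick-breaking p_sel = s(a_sel),
    p_cue = (1 - p_sel) s(a_cue).
    """

    WEIGHT_PRIOR_SD = 1.0
    SIGMA_PRIOR_SD = 10.0

    def __init__(self, activity, designs, behav, epoch, whitener=None):
        self.R = np.asarray(activity, dtype=float)
        self.behav = np.asarray(behav, dtype=float)
        self.epoch = epoch
        self.n, self.D = self.R.shape
        self.P = designs.shape[2]
        self.M = designs.shape[0]
        # Whiten the weight coordinates with the (ridge-regularized) design
        # Gram: the periodic basis is a partition of unity, which makes
        # block sums exactly collinear with the intercepts and leaves flat
        # ridge directions in the raw weight posterior.  Sampling phi with
        # theta = phi @ L^{-1} (L = chol(Gram)) decorrelates those
        # directions; the N(0, 10) prior is placed on phi (a
        # unit-information-style prior on the natural weights).
        if whitener is None:
            whitener = design_whitener(designs, _neutral_gate_weights(behav, epoch))
        self.whitener = whitener
        self.L, self.Linv = self.whitener
        self.designs = designs @ self.Linv.T[None]
        self.n_scalars = 2 if epoch == "delay1" else 3
        self.dim = self.P * self.D + self.D + self.n_scalars

    def unpack(self, x):
        """Unconstrained draws -> (phi, sigma, scalar logits)."""
        PD = self.P * self.D
        theta = x[:PD].reshape(self.D, self.P)
        sigma = np.exp(x[PD : PD + self.D])
        sc = x[PD + self.D :]
        return theta, sigma, sc

    def natural_theta(self, phi):
        """Map whitened weights phi back to natural weights theta."""
        return phi @ self.Linv

    def scalars_dict(self, sc):
        if self.epoch == "delay1":
            return {"p_misbind": _sigmoid(sc[0]), "p_resp": _sigmoid(sc[1])}
        s1, s2 = _sigmoid(sc[0]), _sigmoid(sc[1])
        return {"p_selection": s1, "p_cue": (1 - s1) * s2, "p_resp": _sigmoid(sc[2])}

    def logp_and_grad(self, x):
        with np.errstate(all="ignore"):
            logp, grad = self._logp_and_grad(x)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(x)
        return logp, grad

    def _logp_and_grad(self, x):
        theta, sigma, sc = self.unpack(x)
        scalars = self.scalars_dict(sc)
        w = _component_log_weights(self.behav, self.epoch, scalars)
        lse, gamma, mus = _mixture_loglik_rows(self.R, self.designs, theta, sigma, w)
        logp = float(np.sum(lse))

        inv_var = 1.0 / sigma**2
        g_theta = np.zeros_like(theta)
        g_logsig = np.zeros(self.D)
        for m in range(self.M):
            resid = (self.R - mus[m]) * gamma[:, m : m + 1]
            g_theta += (resid * inv_var).T @ self.designs[m]
            g_logsig += np.sum(((self.R - mus[m]) ** 2 * inv_var - 1.0)
                               * gamma[:, m : m + 1], axis=0)

        pc, ps, pg = self.behav[:, 0], self.behav[:, 1], self.behav[:, 2]
        wn = w[:, 0]
        g_sc = np.zeros(self.n_scalars)
        if self.epoch == "delay1":
            pm, pr = _sigmoid(sc[0]), _sigmoid(sc[1])
            dpm = pm * (1 - pm)
            dpr = pr * (1 - pr)
            g_sc[0] = np.sum(gamma[:, 1] * (1 - pm) - gamma[:, 0] * ps * dpm / wn)
            g_sc[1] = np.sum(gamma[:, 2] * (1 - pr) - gamma[:, 0] * pg * dpr / wn)
        else:
            s1, s2, pr = _sigmoid(sc[0]), _sigmoid(sc[1]), _sigmoid(sc[2])
            # p_sel = s1, p_cue = (1 - s1) s2, 1 - p_sel - p_cue = (1 - s1)(1 - s2)
            dnom_da1 = -ps * s1 * (1 - s1) * (1 - s2)
            dnom_da2 = -ps * (1 - s1) * s2 * (1 - s2)
            g_sc[0] = np.sum(
                gamma[:, 1] * (1 - s1) - gamma[:, 2] * s1 + gamma[:, 0] * dnom_da1 / wn
            )
            g_sc[1] = np.sum(
                gamma[:, 2] * (1 - s2) + gamma[:, 0] * dnom_da2 / wn
            )
            g_sc[2] = np.sum(
                gamma[:, 3] * (1 - pr) - gamma[:, 0] * pg * pr * (1 - pr) / wn
            )

        # priors: theta ~ N(0, 10); sigma ~ half-normal(10), log-scale Jacobian;
        # mixture probabilities uniform via sigmoid/stick-breaking Jacobians.
        tau2 = self.WEIGHT_PRIOR_SD**2
        logp += float(-0.5 * np.sum(theta * theta) / tau2)
        g_theta -= theta / tau2
        st2 = self.SIGMA_PRIOR_SD**2
        logp += float(np.sum(-0.5 * sigma**2 / st2 + np.log(sigma)))
        g_logsig += -(sigma**2) / st2 + 1.0
        s_all = _sigmoid(sc)
        logp += float(np.sum(np.log(s_all) + np.log1p(-s_all)))
        g_sc += 1.0 - 2.0 * s_all
        if self.epoch != "delay1":
            # extra (1 - p_sel) factor of the stick-breaking Jacobian
            logp += float(np.log1p(-s_all[0]))
            g_sc[0] += -s_all[0]

        grad = np.concatenate([g_theta.reshape(-1), g_logsig, g_sc])
        return logp, grad


@dataclass
class MixtureFit:
    """Posterior over mixture scalars and encoder parameters for a session."""

    epoch: str
    result: HMCResult | None
    problem: _MixtureProblem
    scalar_draws: pd.DataFrame  # columns p_misbind/p_selection/p_cue/p_resp
    encoder: Delay1Encoder | Delay2Encoder
    diagnostics: dict
    session_id: str = "s0"
    task_type: str = "retro"

    @property
    def weights(self) -> MixtureWeights:
        means = self.scalar_draws.mean()
        return MixtureWeights(**{k: float(means[k]) for k in self.scalar_draws.columns})

    def alternative_probability_draws(self) -> np.ndarray:
        """Draws of the total alternative-representation probability among
        swap trials (p_misbind for delay 1, p_selection + p_cue for delay 2)."""
        if self.epoch == "delay1":
            return self.scalar_draws["p_misbind"].to_numpy()
        return (self.scalar_draws["p_selection"] + self.scalar_draws["p_cue"]).to_numpy()


class NeuralMixtureModel:
    """sklearn-style estimator for the neural mixture model.

    fit(activity, trials, behav) takes preprocessed activity (trials x
    dims; z-score -> PCA -> z-score path), the trial table, and per-trial
    behavioral posteriors (columns p_correct_post, p_swap_post,
    p_guess_post).  Attributes after fit: ``fit_`` (MixtureFit),
    ``weights_`` (posterior-mean MixtureWeights), ``encoder_``,
    ``diagnostics_``.

    With ``hierarchical=True`` the trial table may mix task types
    (retro / pro / single); encoder weights are then partially pooled
    across types and per-type mixture scalars are returned in ``fits_``.
    """

    def __init__(self, epoch="delay2", chains=4, warmup=500, samples=500,
                 method="mcmc", seed=0, n_knots=5, order=1, max_leapfrog=24,
                 hierarchical=False):
        self.epoch = epoch
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.method = method
        self.seed = seed
        self.n_knots = n_knots
        self.order = order
        self.max_leapfrog = max_leapfrog
        self.hierarchical = hierarchical

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "epoch", "chains", "warmup", "samples", "method", "seed",
            "n_knots", "order", "max_leapfrog", "hierarchical")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _scalar_names(self):
        return (["p_misbind", "p_resp"] if self.epoch == "delay1"
                else ["p_selection", "p_cue", "p_resp"])

    def _fit_group(self, activity, trials, behav, session_id, task_type):
        basis = SplineBasisSpec(self.n_knots, self.order)
        designs, _ = _component_designs(trials, self.epoch, basis)
        prob = _MixtureProblem(activity, designs, behav, self.epoch)
        if not np.any(behav[:, 1] > 1e-6):
            import warnings

            warnings.warn(
                "no trial has swap probability > 0; mixture weights are "
                "unidentifiable and their posteriors reproduce the prior"
            )
        x0 = np.zeros(prob.dim)
        x0[prob.P * prob.D : prob.P * prob.D + prob.D] = np.log(
            np.maximum(activity.std(axis=0), 1e-3)
        )
        x_map = find_map(prob.logp_and_grad, x0)
        inv_mass0 = diag_hessian_inv_mass(prob.logp_and_grad, x_map)
        names = self._scalar_names()
        if self.method == "map":
            phi, sigma, sc = prob.unpack(x_map)
            theta = prob.natural_theta(phi)
            scalars = prob.scalars_dict(sc)
            draws = pd.DataFrame({k: [scalars[k]] for k in names})
            result = None
            diagnostics = {"method": "map"}
        else:
            result = sample_hmc(
                prob.logp_and_grad, x_map, n_chains=self.chains,
                n_warmup=self.warmup, n_samples=self.samples, seed=self.seed,
                max_leapfrog=self.max_leapfrog, inv_mass0=inv_mass0,
            )
            flat = result.flat()
            sc_draws = flat[:, prob.P * prob.D + prob.D :]
            rows = [prob.scalars_dict(s) for s in sc_draws]
            draws = pd.DataFrame(rows)[names]
            theta_mean = prob.natural_theta(
                flat[:, : prob.P * prob.D].mean(axis=0).reshape(prob.D, prob.P))
            sigma_mean = np.exp(flat[:, prob.P * prob.D : prob.P * prob.D + prob.D]).mean(axis=0)
            theta, sigma = theta_mean, sigma_mean
            rhat = split_rhat(result.draws)
            diagnostics = {
                "method": "mcmc",
                "max_rhat": float(np.nanmax(rhat)),
                "scalar_rhat": {
                    n: float(r) for n, r in zip(
                        names, rhat[prob.P * prob.D + prob.D :])
                },
                "n_divergent": result.n_divergent,
                "accept_rate": result.accept_rate,
                "seed": self.seed,
            }
        if self.epoch == "delay1":
            encoder = Delay1Encoder.from_theta(theta, sigma, basis)
        else:
            encoder = Delay2Encoder.from_theta(theta, sigma, basis)
        return MixtureFit(
            epoch=self.epoch, result=result, problem=prob, scalar_draws=draws,
            encoder=encoder, diagnostics=diagnostics, session_id=session_id,
            task_type=task_type,
        )

    def fit(self, activity, trials: pd.DataFrame, behav: pd.DataFrame):
        activity = np.asarray(activity, dtype=float)
        if len(trials) != activity.shape[0] or len(behav) != activity.shape[0]:
            raise ValueError("activity, trials, and behav must align")
        bcols = ["p_correct_post", "p_swap_post", "p_guess_post"]
        behav_arr = behav[bcols].to_numpy(dtype=float)
        sid = str(trials["session_id"].iloc[0]) if "session_id" in trials else "s0"

        if not self.hierarchical:
            self.fit_ = self._fit_group(
                activity, trials.reset_index(drop=True), behav_arr, sid,
                str(trials["task_type"].iloc[0]) if "task_type" in trials else "retro",
            )
            self.fits_ = {self.fit_.task_type: self.fit_}
        else:
            self.fit_, self.fits_ = self._fit_hierarchical(
                activity, trials.reset_index(drop=True), behav_arr, sid
            )
        self.weights_ = self.fit_.weights
        self.encoder_ = self.fit_.encoder
        self.diagnostics_ = self.fit_.diagnostics
        return self

    def _fit_hierarchical(self, activity, trials, behav, sid):
        basis = SplineBasisSpec(self.n_knots, self.order)
        types = [t for t in ("retro", "pro", "single")
                 if (trials["task_type"] == t).any()]
        groups = {}
        for t in types:
            mask = (trials["task_type"] == t).to_numpy()
            designs, _ = _component_designs(
                trials.loc[mask].reset_index(drop=True), self.epoch, basis)
            groups[t] = (activity[mask], designs, behav[mask])
        prob = _HierarchicalMixtureProblem(groups, self.epoch)
        x0 = prob.initial_point()
        x_map = find_map(prob.logp_and_grad, x0)
        inv_mass0 = diag_hessian_inv_mass(prob.logp_and_grad, x_map)
        names = self._scalar_names()
        if self.method == "map":
            flat = x_map[None, :]
            diagnostics = {"method": "map"}
            result = None
        else:
            result = sample_hmc(
                prob.logp_and_grad, x_map, n_chains=self.chains,
                n_warmup=self.warmup, n_samples=self.samples, seed=self.seed,
                max_leapfrog=self.max_leapfrog, inv_mass0=inv_mass0,
            )
            flat = result.flat()
            rhat = split_rhat(result.draws)
            diagnostics = {"method": "mcmc", "max_rhat": float(np.nanmax(rhat)),
                           "n_divergent": result.n_divergent,
                           "accept_rate": result.accept_rate}
        fits = {}
        for t in types:
            sc_draws = np.array([prob.type_scalars(x, t) for x in flat])
            draws = pd.DataFrame(sc_draws, columns=names)
            theta, sigma = prob.type_encoder_params(flat.mean(axis=0), t)
            encoder = (Delay1Encoder if self.epoch == "delay1" else Delay2Encoder) \
                .from_theta(theta, sigma, basis)
            fits[t] = MixtureFit(
                epoch=self.epoch, result=result, problem=None, scalar_draws=draws,
                encoder=encoder, diagnostics=diagnostics, session_id=sid, task_type=t,
            )
        primary = fits.get("retro") or fits[types[0]]
        return primary, fits


class _HierarchicalMixtureProblem:
    """Shared-mean/SD pooling of encoder weights across task types.

    Per-type weights theta_t = theta_mean + theta_sd * Z_t (non-centered);
    theta_mean entries ~ N(0, 10), theta_sd entries ~ half-normal(10),
    Z_t ~ N(0, 1).  Noise SDs and mixture scalars are per type.
    Layout: [theta_mean (PD), log theta_sd (PD),
             per type: (Z_t (PD), log sigma_t (D), scalars_t)].
    """

    def __init__(self, groups: dict, epoch: str):
        self.epoch = epoch
        self.types = list(groups)
        any_designs = next(iter(groups.values()))[1]
        self.M, _, self.P = any_designs.shape
        pooled = np.concatenate([g[1] for g in groups.values()], axis=1)
        pooled_w = np.concatenate(
            [_neutral_gate_weights(g[2], epoch) for g in groups.values()], axis=0)
        self.whitener = design_whitener(pooled, pooled_w)
        self.Linv = self.whitener[1]
        self.groups = groups
        self.D = next(iter(groups.values()))[0].shape[1]
        self.n_scalars = 2 if epoch == "delay1" else 3
        self.PD = self.P * self.D
        self.per_type = self.PD + self.D + self.n_scalars
        self.dim = 2 * self.PD + len(self.types) * self.per_type

    def initial_point(self):
        x0 = np.zeros(self.dim)
        x0[self.PD : 2 * self.PD] = np.log(0.5)
        for i, t in enumerate(self.types):
            base = 2 * self.PD + i * self.per_type
            act = self.groups[t][0]
            x0[base + self.PD : base + self.PD + self.D] = np.log(
                np.maximum(act.std(axis=0), 1e-3))
        return x0

    def _slices(self, i):
        base = 2 * self.PD + i * self.per_type
        return (slice(base, base + self.PD),
                slice(base + self.PD, base + self.PD + self.D),
                slice(base + self.PD + self.D, base + self.per_type))

    def type_encoder_params(self, x, t):
        i = self.types.index(t)
        zs, ss, _ = self._slices(i)
        theta_mean = x[: self.PD]
        theta_sd = np.exp(x[self.PD : 2 * self.PD])
        phi = (theta_mean + theta_sd * x[zs]).reshape(self.D, self.P)
        return phi @ self.Linv, np.exp(x[ss])

    def type_scalars(self, x, t):
        i = self.types.index(t)
        _, _, scs = self._slices(i)
        sc = x[scs]
        if self.epoch == "delay1":
            return [_sigmoid(sc[0]), _sigmoid(sc[1])]
        s1, s2 = _sigmoid(sc[0]), _sigmoid(sc[1])
        return [s1, (1 - s1) * s2, _sigmoid(sc[2])]

    def logp_and_grad(self, x):
        with np.errstate(all="ignore"):
            logp, grad = self._logp_and_grad(x)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(x)
        return logp, grad

    def _logp_and_grad(self, x):
        theta_mean = x[: self.PD]
        log_sd = x[self.PD : 2 * self.PD]
        theta_sd = np.exp(log_sd)
        grad = np.zeros_like(x)
        logp = 0.0
        for i, t in enumerate(self.types):
            act, designs, behav = self.groups[t]
            zs, ss, scs = self._slices(i)
            z = x[zs]
            sub = np.concatenate([theta_mean + theta_sd * z, x[ss], x[scs]])
            prob = _MixtureProblem(act, designs, behav, self.epoch,
                                   whitener=self.whitener)
            # strip the sub-problem's own weight prior; the hierarchy owns it
            prob.WEIGHT_PRIOR_SD = np.inf
            lp, g = prob.logp_and_grad(sub)
            logp += lp
            g_theta = g[: self.PD]
            grad[: self.PD] += g_theta
            grad[self.PD : 2 * self.PD] += g_theta * theta_sd * z
            grad[zs] += g_theta * theta_sd - z
            grad[ss] += g[self.PD : self.PD + self.D]
            grad[scs] += g[self.PD + self.D :]
            logp += float(-0.5 * z @ z)
        tau2 = 1.0
        logp += float(-0.5 * theta_mean @ theta_mean / tau2)
        grad[: self.PD] += -theta_mean / tau2
        logp += float(np.sum(-0.5 * theta_sd**2 / tau2 + log_sd))
        grad[self.PD : 2 * self.PD] += -(theta_sd**2) / tau2 + 1.0
        return logp, grad


def fit_neural_mixture(activity, trials, behav, epoch="delay2", config=None,
                       **kwargs) -> NeuralMixtureModel:
    """Fit the neural mixture model (thin wrapper over NeuralMixtureModel)."""
    if config is not None:
        kwargs.setdefault("chains", config.mcmc_chains)
        kwargs.setdefault("warmup", config.mcmc_warmup)
        kwargs.setdefault("samples", config.mcmc_samples)
        kwargs.setdefault("seed", config.mcmc_seed)
        kwargs.setdefault("n_knots", config.spline_knots)
        kwargs.setdefault("order", config.spline_order)
    return NeuralMixtureModel(epoch=epoch, **kwargs).fit(activity, trials, behav)


def aggregate_posteriors(fits: list[MixtureFit]):
    """Pool scalar posteriors across session fits.

    Returns a dict with the pooled draw DataFrame (equal draw counts per
    session), per-session posterior means, and the per-session total
    alternative-representation probability draws.
    """
    if not fits:
        raise ValueError("need at least one fit")
    epochs = {f.epoch for f in fits}
    if len(epochs) > 1:
        raise ValueError(f"cannot pool fits across epochs {sorted(epochs)}")
    pooled = pd.concat([f.scalar_draws for f in fits], ignore_index=True)
    per_session = pd.DataFrame(
        [f.scalar_draws.mean() for f in fits],
        index=[f.session_id for f in fits],
    )
    alt = {f.session_id: f.alternative_probability_draws() for f in fits}
    return {"pooled": pooled, "per_session": per_session, "alternative": alt}


def epoch_contrast(delay2_fits: list[MixtureFit], delay1_fits: list[MixtureFit]) -> pd.Series:
    """Per-session contrast of total alternative-representation probability,
    delay 2 minus delay 1 (positive when error representations emerge at
    selection rather than during storage)."""
    d2 = {f.session_id: float(np.mean(f.alternative_probability_draws()))
          for f in delay2_fits}
    d1 = {f.session_id: float(np.mean(f.alternative_probability_draws()))
          for f in delay1_fits}
    common = sorted(set(d2) & set(d1))
    return pd.Series({s: d2[s] - d1[s] for s in common})
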