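"""Hierarchical three-component mixture model of continuous color reports.

Each trial's report is modelled as a mixture of a correct response
(wrapped normal around the target color t), a swap response (wrapped
normal around the distractor d, same dispersion), and a uniform guess:

    p_i(r) = p_correct_i N_w(r - t; sigma_i)
           + p_swap_i    N_w(r - d; sigma_i)
           + p_guess_i / (2 pi)

with one (p_swap, p_guess, sigma) triple per session i.  Sessions are
partially pooled within an animal: the session mixture probabilities are
parameterized by logits

    p_guess_i = exp(w_guess_i) / (exp(w_guess_i) + exp(w_swap_i) + 1)

(and symmetrically for swaps) with w_type_i ~ N(w_type, s_type) across
sessions.  Hyper means get N(0, 1) priors; hyper SDs get a normal(1, 3)
prior truncated at zero by default (a location-zero half-normal with
scale 3 is available via ``sd_prior="half-normal"``).  Session dispersions
sigma_i get independent half-normal(1 rad) priors.

Posteriors are sampled with Hamiltonian Monte Carlo in an unconstrained,
non-centered parameterization (session logits expressed as standardized
offsets from the hyper mean, SDs sampled on the log scale with Jacobian
corrections); the default budget is 4 chains x (500 warmup + 500 samples).
A maximum-a-posteriori fast path (``method="map"``) serves quick runs; the
MCMC path is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import (
    TWO_PI,
    _OFFSETS,
    circ_dist,
    wrap_to_pi,
    wrapped_normal_pdf,
    wrapped_normal_sample,
)
from .hmc import HMCResult, diag_hessian_inv_mass, find_map, sample_hmc, split_rhat

UNIFORM_DENSITY = 1.0 / TWO_PI


@dataclass
class SessionBehaviorParams:
    """Per-session mixture probabilities and report dispersion (radians)."""

    p_swap: float
    p_guess: float
    sigma: float
    session_id: str = "s0"

    @property
    def p_correct(self) -> float:
        return 1.0 - self.p_swap - self.p_guess

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.p_swap <= 1 and 0 <= self.p_guess <= 1 and self.p_correct >= -1e-12):
            raise ValueError("mixture probabilities must lie in [0, 1] and sum to <= 1")


@dataclass
class MonkeyHyperParams:
    """Animal-level hyperparameters of the session-logit distribution."""

    w_swap_mean: float
    w_guess_mean: float
    s_swap: float
    s_guess: float

    def __post_init__(self):
        if self.s_swap <= 0 or self.s_guess <= 0:
            raise ValueError("hyper SDs must be positive")


def logits_to_probs(w_swap, w_guess):
    """Softmax transform of session logits: returns (p_swap, p_guess, p_correct).

    p_swap = exp(w_swap) / (exp(w_swap) + exp(w_guess) + 1), the correct
    component carrying the reference logit 0.
    """
    w_swap = np.asarray(w_swap, dtype=float)
    w_guess = np.asarray(w_guess, dtype=float)
    if not (np.all(np.isfinite(w_swap)) and np.all(np.isfinite(w_guess))):
        raise ValueError("logits must be finite")
    m = np.maximum(np.maximum(w_swap, w_guess), 0.0)
    es, eg, e0 = np.exp(w_swap - m), np.exp(w_guess - m), np.exp(-m)
    z = es + eg + e0
    return es / z, eg / z, e0 / z


def response_log_density(c_report, t, d, params: SessionBehaviorParams):
    """Log mixture density of a report given target t and distractor d."""
    e_t = circ_dist(c_report, t)
    e_d = circ_dist(c_report, d)
    f_t = wrapped_normal_pdf(e_t, params.sigma)
    f_d = wrapped_normal_pdf(e_d, params.sigma)
    dens = (
        params.p_correct * f_t + params.p_swap * f_d + params.p_guess * UNIFORM_DENSITY
    )
    return np.log(dens)


def _wrapped_pdf_and_dsigma(err, sigma):
    """Wrapped normal density and its derivative w.r.t. sigma (vectorized)."""
    z = (err[..., None] + _OFFSETS) / sigma[..., None]
    phi = np.exp(-0.5 * z * z) / np.sqrt(TWO_PI)
    f = phi.sum(axis=-1) / sigma
    df = (phi * (z * z - 1.0)).sum(axis=-1) / sigma**2
    return f, df


class _BehaviorPosteriorProblem:
    """Log posterior and gradient in the unconstrained space.

    Layout: [w_s, w_g, log s_s, log s_g, z_s (S), z_g (S), log sigma (S)].
    """

    def __init__(self, e_t, e_d, session_idx, n_sessions, sd_prior="truncated-normal",
                 sigma_prior_scale=1.0):
        self.e_t = e_t
        self.e_d = e_d
        self.idx = session_idx
        self.S = n_sessions
        self.sd_prior = sd_prior
        self.sigma_scale = sigma_prior_scale
        self.dim = 4 + 3 * n_sessions

    def unpack(self, x):
        S = self.S
        return (x[0], x[1], np.exp(x[2]), np.exp(x[3]),
                x[4 : 4 + S], x[4 + S : 4 + 2 * S], np.exp(x[4 + 2 * S :]))

    def session_probs(self, x):
        w_s, w_g, s_s, s_g, z_s, z_g, sigma = self.unpack(x)
        a = w_s + s_s * z_s
        b = w_g + s_g * z_g
        p_s, p_g, p_c = logits_to_probs(a, b)
        return p_s, p_g, p_c, sigma

    def _sd_prior_terms(self, s):
        """(log prior incl. Jacobian, d/dlog s) for a hyper SD."""
        if self.sd_prior == "half-normal":
            return -(s * s) / 18.0 + np.log(s), -(s * s) / 9.0 + 1.0
        # normal(1, 3) truncated at zero (constant normalizer dropped)
        return -((s - 1.0) ** 2) / 18.0 + np.log(s), -(s - 1.0) * s / 9.0 + 1.0

    def logp_and_grad(self, x):
        # extreme warmup proposals can overflow exp(); they surface as a
        # non-finite logp, which the sampler rejects
        try:
            with np.errstate(all="ignore"):
                logp, grad = self._logp_and_grad(x)
        except (ValueError, FloatingPointError):
            return -np.inf, np.zeros_like(x)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(x)
        return logp, grad

    def _logp_and_grad(self, x):
        S = self.S
        w_s, w_g, s_s, s_g, z_s, z_g, sigma = self.unpack(x)
        a = w_s + s_s * z_s
        b = w_g + s_g * z_g
        p_s, p_g, p_c = logits_to_probs(a, b)

        sig_t = sigma[self.idx]
        f_t, df_t = _wrapped_pdf_and_dsigma(self.e_t, sig_t)
        f_d, df_d = _wrapped_pdf_and_dsigma(self.e_d, sig_t)
        pc_t, ps_t, pg_t = p_c[self.idx], p_s[self.idx], p_g[self.idx]
        L = pc_t * f_t + ps_t * f_d + pg_t * UNIFORM_DENSITY
        logp = float(np.sum(np.log(L)))

        inv_L = 1.0 / L
        # d logL / d session logits, accumulated per session
        da_t = ps_t * (f_d - L) * inv_L
        db_t = pg_t * (UNIFORM_DENSITY - L) * inv_L
        dsig_t = (pc_t * df_t + ps_t * df_d) * inv_L
        da = np.bincount(self.idx, weights=da_t, minlength=S)
        db = np.bincount(self.idx, weights=db_t, minlength=S)
        dsig = np.bincount(self.idx, weights=dsig_t, minlength=S)

        grad = np.empty_like(x)
        # hyper means: N(0, 1) priors
        logp += -0.5 * (w_s * w_s + w_g * w_g)
        grad[0] = da.sum() - w_s
        grad[1] = db.sum() - w_g
        # hyper SDs (sampled as log s)
        lp_ss, g_ss = self._sd_prior_terms(s_s)
        lp_sg, g_sg = self._sd_prior_terms(s_g)
        logp += lp_ss + lp_sg
        grad[2] = s_s * np.dot(z_s, da) + g_ss
        grad[3] = s_g * np.dot(z_g, db) + g_sg
        # non-centered offsets: N(0, 1) priors
        logp += -0.5 * float(z_s @ z_s + z_g @ z_g)
        grad[4 : 4 + S] = s_s * da - z_s
        grad[4 + S : 4 + 2 * S] = s_g * db - z_g
        # sigma: half-normal(sigma_scale), sampled as log sigma
        tau2 = self.sigma_scale**2
        logp += float(np.sum(-0.5 * sigma**2 / tau2 + np.log(sigma)))
        grad[4 + 2 * S :] = sigma * dsig - sigma**2 / tau2 + 1.0
        return logp, grad


@dataclass
class BehavioralPosterior:
    """Posterior draws over session and animal-level parameters."""

    result: HMCResult
    session_ids: list[str]
    problem: _BehaviorPosteriorProblem

    @property
    def n_draws(self) -> int:
        return self.result.draws.shape[0] * self.result.draws.shape[1]

    def rhat(self) -> dict[str, float]:
        r = split_rhat(self.result.draws)
        return dict(zip(self.result.param_names, r))

    def session_prob_draws(self):
        """(p_swap, p_guess, p_correct, sigma) arrays of shape (draws, S)."""
        flat = self.result.flat()
        out = [self.problem.session_probs(x) for x in flat]
        p_s = np.array([o[0] for o in out])
        p_g = np.array([o[1] for o in out])
        p_c = np.array([o[2] for o in out])
        sig = np.array([o[3] for o in out])
        return p_s, p_g, p_c, sig

    def session_params(self) -> list[SessionBehaviorParams]:
        """Posterior-mean parameters per session."""
        p_s, p_g, p_c, sig = self.session_prob_draws()
        return [
            SessionBehaviorParams(
                p_swap=float(p_s[:, i].mean()),
                p_guess=float(p_g[:, i].mean()),
                sigma=float(sig[:, i].mean()),
                session_id=self.session_ids[i],
            )
            for i in range(len(self.session_ids))
        ]

    def hyper_params(self) -> MonkeyHyperParams:
        flat = self.result.flat()
        return MonkeyHyperParams(
            w_swap_mean=float(flat[:, 0].mean()),
            w_guess_mean=float(flat[:, 1].mean()),
            s_swap=float(np.exp(flat[:, 2]).mean()),
            s_guess=float(np.exp(flat[:, 3]).mean()),
        )


def _prepare_trials(trials: pd.DataFrame):
    if "t" not in trials.columns or "d" not in trials.columns:
        from .data_model import derive_target_distractor

        trials = derive_target_distractor(trials)
    usable = trials.dropna(subset=["t", "d", "c_report"])
    if len(usable) == 0:
        raise ValueError("no trials with target, distractor, and report")
    session_ids = list(pd.unique(usable["session_id"].astype(str)))
    idx = usable["session_id"].astype(str).map({s: i for i, s in enumerate(session_ids)})
    e_t = circ_dist(usable["c_report"].to_numpy(), usable["t"].to_numpy())
    e_d = circ_dist(usable["c_report"].to_numpy(), usable["d"].to_numpy())
    return usable, e_t, e_d, idx.to_numpy(), session_ids


class HierarchicalBehaviorModel:
    """sklearn-style estimator for the hierarchical behavioral mixture model.

    Parameters
    ----------
    chains, warmup, samples : int
        HMC budget (defaults 4 x (500 + 500)).
    method : {"mcmc", "map"}
        Full posterior sampling (canonical) or a MAP-only fast path.
    sd_prior : {"truncated-normal", "half-normal"}
        Prior family for the hyper SDs s_swap, s_guess.
    sigma_prior_scale : float
        Scale (radians) of the half-normal prior on session dispersions.
    seed : int
        Sampler seed.

    Attributes (after fit)
    ----------------------
    posterior_ : BehavioralPosterior (None when method="map")
    session_params_ : list of SessionBehaviorParams (posterior means / MAP)
    hyper_ : MonkeyHyperParams
    diagnostics_ : dict with per-parameter rhat, max rhat, divergences
    """

    def __init__(self, chains=4, warmup=500, samples=500, method="mcmc",
                 sd_prior="truncated-normal", sigma_prior_scale=1.0, seed=0,
                 max_leapfrog=24):
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.method = method
        self.sd_prior = sd_prior
        self.sigma_prior_scale = sigma_prior_scale
        self.seed = seed
        self.max_leapfrog = max_leapfrog

    def get_params(self, deep=True):
        return {
            "chains": self.chains, "warmup": self.warmup, "samples": self.samples,
            "method": self.method, "sd_prior": self.sd_prior,
            "sigma_prior_scale": self.sigma_prior_scale, "seed": self.seed,
            "max_leapfrog": self.max_leapfrog,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame):
        usable, e_t, e_d, idx, session_ids = _prepare_trials(trials)
        S = len(session_ids)
        prob = _BehaviorPosteriorProblem(
            e_t, e_d, idx, S, sd_prior=self.sd_prior,
            sigma_prior_scale=self.sigma_prior_scale,
        )
        names = (
            ["w_swap", "w_guess", "log_s_swap", "log_s_guess"]
            + [f"z_swap[{s}]" for s in session_ids]
            + [f"z_guess[{s}]" for s in session_ids]
            + [f"log_sigma[{s}]" for s in session_ids]
        )
        x0 = np.zeros(prob.dim)
        x0[0] = x0[1] = -1.0
        x0[2] = x0[3] = np.log(0.5)
        x0[4 + 2 * S :] = np.log(0.4)
        x_map = find_map(prob.logp_and_grad, x0)

        self.problem_ = prob
        self.session_ids_ = session_ids
        self.n_trials_ = len(usable)
        if self.method == "map":
            self.posterior_ = None
            p_s, p_g, p_c, sigma = prob.session_probs(x_map)
            self.session_params_ = [
                SessionBehaviorParams(float(p_s[i]), float(p_g[i]), float(sigma[i]),
                                      session_ids[i])
                for i in range(S)
            ]
            self.hyper_ = MonkeyHyperParams(
                x_map[0], x_map[1], float(np.exp(x_map[2])), float(np.exp(x_map[3]))
            )
            self.map_x_ = x_map
            self.diagnostics_ = {"method": "map"}
            return self

        inv_mass0 = diag_hessian_inv_mass(prob.logp_and_grad, x_map)
        result = sample_hmc(
            prob.logp_and_grad, x_map,
            n_chains=self.chains, n_warmup=self.warmup, n_samples=self.samples,
            seed=self.seed, max_leapfrog=self.max_leapfrog, param_names=names,
            inv_mass0=inv_mass0,
        )
        post = BehavioralPosterior(result, session_ids, prob)
        self.posterior_ = post
        self.session_params_ = post.session_params()
        self.hyper_ = post.hyper_params()
        rhat = post.rhat()
        max_rhat = float(max(rhat.values()))
        self.diagnostics_ = {
            "method": "mcmc",
            "rhat": rhat,
            "max_rhat": max_rhat,
            "converged": max_rhat <= 1.05,
            "n_divergent": result.n_divergent,
            "accept_rate": result.accept_rate,
            "seed": self.seed,
        }
        return self

    def _check_fitted(self):
        if not hasattr(self, "session_params_"):
            raise RuntimeError("model is not fitted")

    def predict_proba(self, trials: pd.DataFrame, draw_averaged: bool | None = None):
        """Per-trial response-type posteriors p(type | report), Bayes rule.

        Returns a DataFrame with columns p_correct_post, p_swap_post,
        p_guess_post (rows sum to 1).  With a full posterior the per-draw
        type probabilities are averaged over draws; with MAP parameters
        the plug-in values are returned.
        """
        self._check_fitted()
        usable, e_t, e_d, idx, session_ids = _prepare_trials(trials)
        lookup = {s: i for i, s in enumerate(self.session_ids_)}
        try:
            col = np.array([lookup[str(s)] for s in usable["session_id"]])
        except KeyError as err:
            raise ValueError(f"unknown session {err}") from None

        if draw_averaged is None:
            draw_averaged = self.posterior_ is not None
        if draw_averaged and self.posterior_ is not None:
            p_s, p_g, p_c, sig = self.posterior_.session_prob_draws()
            acc = np.zeros((len(usable), 3))
            n_draws = p_s.shape[0]
            chunk = 200
            for lo in range(0, n_draws, chunk):
                hi = min(lo + chunk, n_draws)
                acc += _type_posteriors_batch(
                    e_t, e_d, p_c[lo:hi][:, col], p_s[lo:hi][:, col],
                    p_g[lo:hi][:, col], sig[lo:hi][:, col]
                ).sum(axis=0)
            post = acc / n_draws
        else:
            params = {p.session_id: p for p in self.session_params_}
            p_c = np.array([params[str(s)].p_correct for s in usable["session_id"]])
            p_s = np.array([params[str(s)].p_swap for s in usable["session_id"]])
            p_g = np.array([params[str(s)].p_guess for s in usable["session_id"]])
            sig = np.array([params[str(s)].sigma for s in usable["session_id"]])
            post = _type_posteriors_batch(
                e_t, e_d, p_c[None], p_s[None], p_g[None], sig[None]
            )[0]
        return pd.DataFrame(
            post, columns=["p_correct_post", "p_swap_post", "p_guess_post"],
            index=usable.index,
        )


def _type_posteriors_batch(e_t, e_d, p_c, p_s, p_g, sigma):
    """Type posteriors for (draws, trials) parameter arrays; returns (D, T, 3)."""
    f_t = wrapped_normal_pdf(np.broadcast_to(e_t, sigma.shape), sigma)
    f_d = wrapped_normal_pdf(np.broadcast_to(e_d, sigma.shape), sigma)
    num = np.stack([p_c * f_t, p_s * f_d, p_g * UNIFORM_DENSITY], axis=-1)
    return num / num.sum(axis=-1, keepdims=True)


def type_posteriors_from_params(trials: pd.DataFrame,
                                params: SessionBehaviorParams) -> pd.DataFrame:
    """Per-trial type posteriors under known (e.g. generating) parameters."""
    from .data_model import derive_target_distractor

    if "t" not in trials.columns:
        trials = derive_target_distractor(trials)
    e_t = circ_dist(trials["c_report"].to_numpy(dtype=float), trials["t"].to_numpy(dtype=float))
    e_d_raw = trials["d"].to_numpy(dtype=float)
    has_d = ~np.isnan(e_d_raw)
    e_d = circ_dist(trials["c_report"].to_numpy(dtype=float), np.nan_to_num(e_d_raw))
    const = lambda v: np.full(len(trials), float(v))[None]
    post = _type_posteriors_batch(
        e_t, e_d, const(params.p_correct), np.where(has_d, params.p_swap, 0.0)[None],
        const(params.p_guess), const(params.sigma),
    )[0]
    post = post / post.sum(axis=1, keepdims=True)
    return pd.DataFrame(post, columns=["p_correct_post", "p_swap_post", "p_guess_post"],
                        index=trials.index)


def fit_behavioral_model(trials: pd.DataFrame, config=None, **kwargs) -> HierarchicalBehaviorModel:
    """Fit the hierarchical behavioral mixture model (thin wrapper)."""
    if config is not None:
        kwargs.setdefault("chains", config.mcmc_chains)
        kwargs.setdefault("warmup", config.mcmc_warmup)
        kwargs.setdefault("samples", config.mcmc_samples)
        kwargs.setdefault("seed", config.mcmc_seed)
    return HierarchicalBehaviorModel(**kwargs).fit(trials)


def trial_type_posteriors(model: HierarchicalBehaviorModel, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial p(correct/swap/guess | report) under a fitted model."""
    return model.predict_proba(trials)


def posterior_predictive(params: SessionBehaviorParams, trials: pd.DataFrame,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample reports from the inverse model: per trial draw a response type
    (correct/swap/guess), then an error around t, d, or uniform; returns
    simulated reports wrapped onto [0, 2pi)."""
    from .data_model import derive_target_distractor

    if "t" not in trials.columns:
        trials = derive_target_distractor(trials)
    n = len(trials)
    t = trials["t"].to_numpy(dtype=float)
    d = trials["d"].to_numpy(dtype=float)
    types = rng.choice(
        3, size=n, p=[params.p_correct, params.p_swap, params.p_guess]
    )
    err = wrapped_normal_sample(rng, params.sigma, size=n)
    report = np.where(types == 0, t + err, np.where(types == 1, d + err, 0.0))
    uniform = rng.uniform(-np.pi, np.pi, size=n)
    report = np.where(types == 2, uniform, report)
    return np.mod(report, TWO_PI)
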