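"""Hamiltonian Monte Carlo with step-size and diagonal mass adaptation.

A compact gradient-based MCMC engine used by the hierarchical behavioral
model and the neural mixture model.  Models supply ``logp_and_grad(x)``
returning the unnormalized log posterior density and its gradient in an
unconstrained parameterization; constrained parameters are handled by the
models via transforms with Jacobian corrections.

Adaptation follows standard practice: dual averaging of the leapfrog step
size toward a target acceptance rate (Hoffman & Gelman's schedule), with a
windowed re-estimation of a diagonal mass matrix from warmup draws.  The
number of leapfrog steps is jittered uniformly to decorrelate trajectory
lengths.  Convergence is monitored with the split-chain Gelman-Rubin
statistic (r-hat) and effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    """Posterior draws and sampler diagnostics.

    draws has shape (chains, samples, dim), in the unconstrained space the
    model sampled in; models transform back to natural parameters.
    """

    draws: np.ndarray
    accept_rate: float
    step_sizes: np.ndarray
    n_divergent: int
    seed: int
    param_names: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def flat(self) -> np.ndarray:
        """All draws pooled across chains: (chains * samples, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def rhat(self) -> np.ndarray:
        """Split-chain r-hat per dimension."""
        return split_rhat(self.draws)

    def ess(self) -> np.ndarray:
        """Bulk effective sample size per dimension (via arviz)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az

            return np.asarray(
                [az.ess(self.draws[:, :, j]) for j in range(self.draws.shape[-1])]
            )


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    draws: (chains, samples, dim).  Each chain is split in half, giving 2m
    sequences; r-hat = sqrt(((n-1)/n * W + B/n) / W) per dimension, equal
    to 1 when all sequences share the same distribution.
    """
    chains, n, dim = draws.shape
    half = n // 2
    seqs = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, n2 = seqs.shape[0], seqs.shape[1]
    means = seqs.mean(axis=1)  # (2m, dim)
    variances = seqs.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B = n2 * means.var(axis=0, ddof=1)
    var_plus = (n2 - 1) / n2 * W + B / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


def _leapfrog(logp_and_grad: LogpGrad, x, p, grad, eps, inv_mass, n_steps):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * inv_mass * p
        logp, grad = logp_and_grad(x)
        if not np.isfinite(logp):
            return x, p, logp, grad
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _find_initial_step(logp_and_grad, x, inv_mass, rng):
    """Coarse step-size heuristic: double/halve until acceptance crosses 0.5."""
    eps = 0.1
    logp, grad = logp_and_grad(x)
    p = rng.normal(size=x.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(inv_mass * p * p)
    x1, p1, logp1, _ = _leapfrog(logp_and_grad, x, p, grad, eps, inv_mass, 1)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        x1, p1, logp1, _ = _leapfrog(logp_and_grad, x, p, grad, eps, inv_mass, 1)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def sample_hmc(
    logp_and_grad: LogpGrad,
    x0: np.ndarray,
    *,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_samples: int = 500,
    seed: int = 0,
    max_leapfrog: int = 24,
    target_accept: float = 0.85,
    init_jitter: float = 0.5,
    inv_mass0: np.ndarray | None = None,
    param_names: list[str] | None = None,
) -> HMCResult:
    """Run HMC chains and return draws with diagnostics.

    x0 may be a single starting point (each chain jitters it with
    independent normal(0, init_jitter) noise, scaled per coordinate by
    sqrt(inv_mass0) when an initial mass guess is supplied) or one point
    per chain.  ``inv_mass0`` (posterior variance guess per coordinate,
    e.g. from the MAP Hessian diagonal) preconditions the first warmup
    window; later windows re-estimate it from warmup draws.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    dim = x0.shape[1]
    rng = np.random.default_rng(seed)
    jitter_scale = np.sqrt(inv_mass0) if inv_mass0 is not None else np.ones(dim)
    draws = np.empty((n_chains, n_samples, dim))
    total_accept, total_div = 0.0, 0
    step_sizes = np.empty(n_chains)

    # mass re-estimation points within warmup (fractions of warmup length)
    w1 = max(1, int(0.35 * n_warmup))
    w2 = max(w1 + 1, int(0.85 * n_warmup))

    for chain in range(n_chains):
        start = x0[chain % x0.shape[0]] + init_jitter * jitter_scale * rng.normal(size=dim)
        x = start.copy()
        logp, grad = logp_and_grad(x)
        if not np.isfinite(logp):
            raise ValueError("initial point has non-finite log density")
        inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, dtype=float)
        eps = _find_initial_step(logp_and_grad, x, inv_mass, rng)
        # dual-averaging state
        mu, log_eps_bar, h_bar = np.log(10 * eps), 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        da_iter = 0
        window: list[np.ndarray] = []
        accepts = []

        for it in range(n_warmup + n_samples):
            adapting = it < n_warmup
            p = rng.normal(size=dim) / np.sqrt(inv_mass)
            h0 = logp - 0.5 * np.sum(inv_mass * p * p)
            n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
            x_new, p_new, logp_new, grad_new = _leapfrog(
                logp_and_grad, x, p, grad, eps, inv_mass, n_steps
            )
            if np.isfinite(logp_new):
                h1 = logp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
                log_alpha = min(0.0, h1 - h0)
                alpha = np.exp(log_alpha)
                if h0 - h1 > 1000:
                    total_div += adapting is False
                    alpha = 0.0
            else:
                alpha = 0.0
            if rng.random() < alpha:
                x, logp, grad = x_new, logp_new, grad_new

            if adapting:
                da_iter += 1
                frac = 1.0 / (da_iter + t0)
                h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
                log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
                w = da_iter**-kappa
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = np.exp(log_eps)
                window.append(x.copy())
                if it + 1 in (w1, w2):
                    tail = np.asarray(window[len(window) // 2 :])
                    var = tail.var(axis=0, ddof=1) if len(tail) > 4 else inv_mass
                    # guard against coordinates frozen within the window
                    inv_mass = np.clip(np.maximum(var, 1e-3 * inv_mass), 1e-10, None)
                    window.clear()
                    eps = _find_initial_step(logp_and_grad, x, inv_mass, rng)
                    mu, log_eps_bar, h_bar, da_iter = np.log(10 * eps), 0.0, 0.0, 0
                if it + 1 == n_warmup:
                    eps = np.exp(log_eps_bar)
            else:
                accepts.append(alpha)
                draws[chain, it - n_warmup] = x

        total_accept += float(np.mean(accepts))
        step_sizes[chain] = eps

    return HMCResult(
        draws=draws,
        accept_rate=total_accept / n_chains,
        step_sizes=step_sizes,
        n_divergent=total_div,
        seed=seed,
        param_names=param_names or [f"x{j}" for j in range(dim)],
    )


def diag_hessian_inv_mass(logp_and_grad: LogpGrad, x: np.ndarray,
                          eps: float = 1e-4) -> np.ndarray:
    """Inverse-mass guess: 1 / |diagonal Hessian| of -logp at x (typically
    the MAP), via central differences of the gradient."""
    x = np.asarray(x, dtype=float)
    diag = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = eps
        g_plus = logp_and_grad(x + e)[1][i]
        g_minus = logp_and_grad(x - e)[1][i]
        diag[i] = -(g_plus - g_minus) / (2 * eps)
    diag = np.abs(diag)
    floor = max(1e-12, 1e-6 * np.median(diag[diag > 0])) if np.any(diag > 0) else 1.0
    return 1.0 / np.maximum(diag, floor)


def find_map(logp_and_grad: LogpGrad, x0: np.ndarray, maxiter: int = 2000) -> np.ndarray:
    """Posterior mode in the unconstrained space (L-BFGS on -logp)."""
    from scipy.optimize import minimize

    def neg(x):
        lp, g = logp_and_grad(x)
        return -lp, -g

    res = minimize(neg, np.asarray(x0, dtype=float), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return res.x
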