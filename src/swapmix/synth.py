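"""Synthetic behavioral and neural sessions with known ground truth.

The generator emulates the delayed-estimation color task: two colors
drawn independently and uniformly from 64 points on the hue circle, a
binary cue, and a continuous color report that is a three-component
mixture (correct / swap / guess).  Session mixture probabilities are
drawn from the hierarchical logit prior; the report dispersion is a
wrapped normal.

Population activity is generated by the linear spline encoding models.
Correct trials carry the nominal model mean; swap trials carry the
prototype dictated by the trial's mechanism label:

* ``misbind``   — colors swapped at/after encoding: r(l, u) in delay 1 and
  the role-swapped mean r(l, u, c) in delay 2;
* ``misselect`` — storage intact (nominal in delay 1), wrong color
  retrieved at selection: r(l, u, c) in delay 2;
* ``miscue``    — storage intact, cue misread: r(u, l, 1 - c) in delay 2;
* ``none``      — a behavioral swap with no distinct neural signature: the
  nominal mean in every epoch (the null hypothesis for recovery tests).

Guess trials carry, with probability ``p_resp_true``, the mean in which
the reported color replaces the target color (otherwise the nominal
mean).  Per-unit noise is independent Gaussian with a common SD; counts
are emitted by rounding rectified noisy rates about a baseline (the
downstream analyses z-score, so the discretization law is documented but
not critical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import SessionBehaviorParams, logits_to_probs
from .circular import TWO_PI, color_grid, wrap_to_2pi, wrapped_normal_sample
from .data_model import NeuralEpoch, derive_target_distractor, validate_trials
from .encoders import (
    Delay1Encoder,
    Delay2Encoder,
    delay1_design,
    delay2_design,
)
from .splines import SplineBasisSpec, spline_basis

MECHANISMS = ("misbind", "misselect", "miscue", "none")


@dataclass
class GeneratorSpec:
    """Study-condition parameters of the synthetic generator.

    Defaults reproduce the simulated recovery conditions the package is
    validated under: 10 sessions x 600 retrospective trials, hierarchical
    behavioral truth w_swap = -1.8, w_guess = -1.5, s_swap = s_guess = 0.3
    (about 12% swaps and 14% guesses per session), report dispersion
    0.35 rad; 60 units driven by K = 5 linear spline encoders with
    Gaussian unit noise, swap mechanisms 70% selection / 30% cue
    misinterpretation, and prototype separation two noise SDs.
    """

    n_sessions: int = 10
    trials_per_session: int = 600
    task_mix: dict = field(default_factory=lambda: {"retro": 1.0})
    w_swap: float = -1.8
    w_guess: float = -1.5
    s_swap: float = 0.3
    s_guess: float = 0.3
    sigma_behavior: float = 0.35
    n_colors: int = 64
    n_units: int = 60
    n_knots: int = 5
    spline_order: int = 1
    weight_scale: float = 1.0
    noise_sd: float = 2.0
    baseline: float = 20.0
    target_separation: float | None = 2.0  # in noise-SD units; None = raw scale
    mechanism_mix: dict = field(
        default_factory=lambda: {"misbind": 0.0, "misselect": 0.7, "miscue": 0.3,
                                 "none": 0.0}
    )
    p_resp_true: float = 0.5
    n_timecourse_bins: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_session <= 0:
            raise ValueError("trials_per_session must be positive")
        if self.sigma_behavior <= 0:
            raise ValueError("sigma_behavior must be positive")
        mix = {m: self.mechanism_mix.get(m, 0.0) for m in MECHANISMS}
        total = sum(mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("mechanism_mix must sum to 1")
        if any(v < 0 or v > 1 for v in mix.values()):
            raise ValueError("mechanism_mix fractions must lie in [0, 1]")
        if not np.isclose(sum(self.task_mix.values()), 1.0):
            raise ValueError("task_mix must sum to 1")
        if not 0 <= self.p_resp_true <= 1:
            raise ValueError("p_resp_true must lie in [0, 1]")
        self.mechanism_mix = mix

    @property
    def basis(self) -> SplineBasisSpec:
        return SplineBasisSpec(self.n_knots, self.spline_order)


@dataclass
class SessionGroundTruth:
    """Everything the generator knows that the analyses must recover."""

    params: SessionBehaviorParams
    type_labels: np.ndarray        # "correct" / "swap" / "guess" per trial
    mechanism_labels: np.ndarray   # mechanism per swap trial, "" otherwise
    guess_reported: np.ndarray     # bool: guess trial carries reported-color mean
    encoder1: Delay1Encoder | None = None
    encoder2: Delay2Encoder | None = None
    rates: dict = field(default_factory=dict)  # noiseless means per epoch
    mixture_weights: dict = field(default_factory=dict)


def generate_task_trials(spec: GeneratorSpec, rng: np.random.Generator,
                         session_id: str = "s000") -> pd.DataFrame:
    """Draw one session's stimuli: independent uniform colors from the
    64-point grid, Bernoulli(0.5) cue, task types per the configured mix."""
    n = spec.trials_per_session
    grid = color_grid(spec.n_colors)
    tasks = list(spec.task_mix)
    probs = np.array([spec.task_mix[t] for t in tasks])
    task_type = rng.choice(tasks, size=n, p=probs)
    u = grid[rng.integers(0, spec.n_colors, size=n)].astype(float)
    l = grid[rng.integers(0, spec.n_colors, size=n)].astype(float)
    c = rng.integers(0, 2, size=n)
    single = task_type == "single"
    # single-stimulus trials carry only the cued color
    u = np.where(single & (c == 0), np.nan, u)
    l = np.where(single & (c == 1), np.nan, l)
    trials = pd.DataFrame(
        {
            "session_id": session_id,
            "trial_id": np.arange(n),
            "task_type": task_type,
            "u": u,
            "l": l,
            "c": c,
            "c_report": 0.0,
            "response_time": np.nan,
        }
    )
    return derive_target_distractor(trials)


def draw_session_params(spec: GeneratorSpec, rng: np.random.Generator,
                        session_id: str) -> SessionBehaviorParams:
    """One session's mixture probabilities from the hierarchical prior."""
    w_s = spec.w_swap + spec.s_swap * rng.normal()
    w_g = spec.w_guess + spec.s_guess * rng.normal()
    p_s, p_g, _ = logits_to_probs(w_s, w_g)
    return SessionBehaviorParams(float(p_s), float(p_g), spec.sigma_behavior, session_id)


def generate_behavioral_responses(trials: pd.DataFrame, params: SessionBehaviorParams,
                                  rng: np.random.Generator,
                                  mechanism_mix: dict | None = None,
                                  p_resp_true: float = 0.5):
    """Draw response types and continuous reports; returns (trials, truth).

    Single-stimulus trials cannot swap: their type is drawn between
    correct and guess with renormalized probabilities.
    """
    trials = trials.copy()
    n = len(trials)
    p = np.array([params.p_correct, params.p_swap, params.p_guess])
    types = rng.choice(np.array(["correct", "swap", "guess"]), size=n, p=p)
    single = (trials["task_type"] == "single").to_numpy()
    if single.any():
        p2 = np.array([params.p_correct, params.p_guess])
        p2 = p2 / p2.sum()
        redraw = rng.choice(np.array(["correct", "guess"]), size=int(single.sum()), p=p2)
        types = types.copy()
        types[single] = redraw

    t = trials["t"].to_numpy(dtype=float)
    d = trials["d"].to_numpy(dtype=float)
    err = wrapped_normal_sample(rng, params.sigma, size=n)
    report = np.where(types == "correct", t + err,
                      np.where(types == "swap", d + err, 0.0))
    report = np.where(types == "guess", rng.uniform(0, TWO_PI, size=n), report)
    trials["c_report"] = wrap_to_2pi(report)
    trials = derive_target_distractor(trials)

    default_mix = {"misbind": 0.0, "misselect": 0.7, "miscue": 0.3}
    mix = {m: (mechanism_mix or default_mix).get(m, 0.0) for m in MECHANISMS}
    mech = np.full(n, "", dtype=object)
    is_swap = types == "swap"
    if is_swap.any():
        mech[is_swap] = rng.choice(
            np.array(MECHANISMS), size=int(is_swap.sum()),
            p=np.array([mix[m] for m in MECHANISMS]),
        )
    guess_rep = np.zeros(n, dtype=bool)
    is_guess = types == "guess"
    guess_rep[is_guess] = rng.random(int(is_guess.sum())) < p_resp_true

    truth = SessionGroundTruth(
        params=params,
        type_labels=types.astype(object),
        mechanism_labels=mech,
        guess_reported=guess_rep,
        mixture_weights={
            "p_misbind": mix["misbind"],
            "p_selection": mix["misbind"] + mix["misselect"],
            "p_cue": mix["miscue"],
            "p_resp": p_resp_true,
        },
    )
    return trials, truth


def sample_encoders(spec: GeneratorSpec, rng: np.random.Generator):
    """Sample ground-truth delay-1 and delay-2 encoders (Gaussian weights)."""
    K, N, s = spec.n_knots, spec.n_units, spec.weight_scale
    basis = spec.basis
    sig = np.full(N, max(spec.noise_sd, 1e-12))
    enc1 = Delay1Encoder(
        W_u=s * rng.normal(size=(N, K)), W_l=s * rng.normal(size=(N, K)),
        sigma=sig.copy(), basis=basis,
    )
    enc2 = Delay2Encoder(
        W_ut=s * rng.normal(size=(N, K)), W_ud=s * rng.normal(size=(N, K)),
        W_lt=s * rng.normal(size=(N, K)), W_ld=s * rng.normal(size=(N, K)),
        b_0=s * rng.normal(size=N), b_1=s * rng.normal(size=N),
        sigma=sig.copy(), basis=basis,
    )
    return enc1, enc2


def _scale_weights(encoder, factor):
    for name in ("W_u", "W_l", "W_ut", "W_ud", "W_lt", "W_ld"):
        if hasattr(encoder, name):
            setattr(encoder, name, getattr(encoder, name) * factor)


def calibrate_separation(encoder, trials: pd.DataFrame, epoch: str,
                         target: float, noise_sd: float) -> float:
    """Scale encoder weights so the median Euclidean separation between the
    nominal and the alternative (color-swapped) prototype equals
    ``target * noise_sd`` across the session's two-stimulus trials.
    Returns the applied factor."""
    two = trials.dropna(subset=["u", "l"])
    u = two["u"].to_numpy(dtype=float)
    l = two["l"].to_numpy(dtype=float)
    c = two["c"].to_numpy()
    if epoch == "delay1":
        nom = delay1_design(u, l, encoder.basis) @ encoder.theta.T
        alt = delay1_design(l, u, encoder.basis) @ encoder.theta.T
    else:
        nom = delay2_design(u, l, c, encoder.basis) @ encoder.theta.T
        alt = delay2_design(l, u, c, encoder.basis) @ encoder.theta.T
    sep = np.linalg.norm(nom - alt, axis=1)
    sep = sep[sep > 1e-9]
    med = float(np.median(sep)) if len(sep) else 1.0
    factor = (target * max(noise_sd, 1e-12)) / med if med > 0 else 1.0
    _scale_weights(encoder, factor)
    return factor


def _effective_conditions(trials: pd.DataFrame, truth: SessionGroundTruth, epoch: str):
    """Per-trial (u', l', c') after mechanism substitution for ``epoch``."""
    u = trials["u"].to_numpy(dtype=float).copy()
    l = trials["l"].to_numpy(dtype=float).copy()
    c = trials["c"].to_numpy().copy()
    rep = trials["c_report"].to_numpy(dtype=float)
    mech = truth.mechanism_labels
    types = truth.type_labels

    if epoch == "delay1":
        swap_mask = (types == "swap") & (mech == "misbind")
    else:
        swap_mask = (types == "swap") & np.isin(mech, ("misbind", "misselect"))
        cue_mask = (types == "swap") & (mech == "miscue")
        c = np.where(cue_mask, 1 - c, c)
    u2 = np.where(swap_mask, l, u)
    l2 = np.where(swap_mask, u, l)

    g = (types == "guess") & truth.guess_reported
    # reported color replaces the target-role color
    u2 = np.where(g & (c == 1), rep, u2)
    l2 = np.where(g & (c == 0), rep, l2)
    return u2, l2, c


def _epoch_means(trials, truth, encoder, epoch):
    u2, l2, c2 = _effective_conditions(trials, truth, epoch)
    if epoch == "delay1":
        fu = np.where(np.isnan(u2)[:, None], 0.0,
                      spline_basis(np.nan_to_num(u2), encoder.basis))
        fl = np.where(np.isnan(l2)[:, None], 0.0,
                      spline_basis(np.nan_to_num(l2), encoder.basis))
        X = np.concatenate([fu, fl], axis=1)
    else:
        X = delay2_design(u2, l2, c2, encoder.basis)
    return X @ encoder.theta.T


def generate_population_activity(trials: pd.DataFrame, truth: SessionGroundTruth,
                                 encoder1: Delay1Encoder, encoder2: Delay2Encoder,
                                 spec: GeneratorSpec, rng: np.random.Generator):
    """Noisy spike-count epochs driven by the encoding models.

    Returns ``{"delay1": NeuralEpoch, "delay2": NeuralEpoch}`` (plus a
    ``timecourse`` epoch when ``spec.n_timecourse_bins > 0``) and records
    the noiseless means in ``truth.rates``.
    """
    n, N = len(trials), spec.n_units
    if encoder1.n_dims != N or encoder2.n_dims != N:
        raise ValueError("encoder dimensionality does not match n_units")
    epochs: dict[str, NeuralEpoch] = {}
    means = {
        "delay1": spec.baseline + _epoch_means(trials, truth, encoder1, "delay1"),
        "delay2": spec.baseline + _epoch_means(trials, truth, encoder2, "delay2"),
    }
    truth.rates = means
    truth.encoder1, truth.encoder2 = encoder1, encoder2
    for name, align in (("delay1", "stimuli_on"), ("delay2", "cue_on")):
        noisy = means[name] + spec.noise_sd * rng.normal(size=(n, N))
        counts = np.rint(np.clip(noisy, 0, None)).astype(np.int32)
        epochs[name] = NeuralEpoch(
            counts=counts[:, :, None],
            bin_edges=np.array([0.5, 1.0]),
            alignment_event=align,
        )
    if spec.n_timecourse_bins > 0:
        B = spec.n_timecourse_bins
        width = 0.25
        edges = -width * (B // 2) + width * np.arange(B + 1)
        centers = (edges[:-1] + edges[1:]) / 2
        counts = np.empty((n, N, B), dtype=np.int32)
        for b, ctr in enumerate(centers):
            mu = means["delay1"] if ctr < 0 else means["delay2"]
            noisy = mu + spec.noise_sd * rng.normal(size=(n, N))
            counts[:, :, b] = np.rint(np.clip(noisy, 0, None)).astype(np.int32)
        epochs["timecourse"] = NeuralEpoch(
            counts=counts, bin_edges=edges, alignment_event="cue_on"
        )
    return epochs


@dataclass
class GeneratedSession:
    trials: pd.DataFrame
    epochs: dict
    truth: SessionGroundTruth


def generate_session(spec: GeneratorSpec, rng: np.random.Generator,
                     session_index: int = 0, with_neural: bool = True,
                     encoders=None) -> GeneratedSession:
    """Generate one complete session (behavior and, optionally, activity)."""
    sid = f"s{session_index:03d}"
    trials = generate_task_trials(spec, rng, session_id=sid)
    params = draw_session_params(spec, rng, sid)
    trials, truth = generate_behavioral_responses(
        trials, params, rng, mechanism_mix=spec.mechanism_mix,
        p_resp_true=spec.p_resp_true,
    )
    epochs: dict = {}
    if with_neural:
        if encoders is None:
            enc1, enc2 = sample_encoders(spec, rng)
            if spec.target_separation is not None:
                calibrate_separation(enc1, trials, "delay1",
                                     spec.target_separation, spec.noise_sd)
                calibrate_separation(enc2, trials, "delay2",
                                     spec.target_separation, spec.noise_sd)
        else:
            enc1, enc2 = encoders
        epochs = generate_population_activity(trials, truth, enc1, enc2, spec, rng)
    trials = validate_trials(trials)
    return GeneratedSession(trials=trials, epochs=epochs, truth=truth)


def generate_study(spec: GeneratorSpec, with_neural: bool = False):
    """Generate ``spec.n_sessions`` sessions; returns (trials, sessions).

    ``trials`` is the concatenated trial table across sessions (the input
    the hierarchical behavioral fit consumes); ``sessions`` the per-session
    GeneratedSession list with ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    sessions = [
        generate_session(spec, rng, i, with_neural=with_neural)
        for i in range(spec.n_sessions)
    ]
    trials = pd.concat([s.trials for s in sessions], ignore_index=True)
    return trials, sessions


def make_correlation_data(eig_shares, n: int, rng: np.random.Generator | None = None
                          ) -> np.ndarray:
    """Data matrix whose sample correlation matrix has exactly the given
    eigenvalue shares (columns have unit sample variance, so a per-column
    z-score is a no-op and PCA sees exactly these variance fractions).

    Built from an orthonormal score basis and a rotation balanced by Givens
    sweeps so every column variance equals 1.
    """
    shares = np.asarray(eig_shares, dtype=float)
    if not np.isclose(shares.sum(), 1.0):
        raise ValueError("eigenvalue shares must sum to 1")
    p = len(shares)
    if n <= p:
        raise ValueError("need more rows than columns")
    eigs = shares * p
    rng = rng or np.random.default_rng(0)
    raw = rng.normal(size=(n, p))
    raw -= raw.mean(axis=0)
    E, _ = np.linalg.qr(raw)          # orthonormal, zero-mean score columns
    Q = np.eye(p)
    for _ in range(60):               # balance diag(Q D Q^T) to all-equal
        M = Q @ np.diag(eigs) @ Q.T
        d = np.diag(M)
        i, j = int(np.argmax(d)), int(np.argmin(d))
        if d[i] - d[j] < 1e-14:
            break
        # Givens angle equalizing entries (i, i) and (j, j)
        a, b, c2 = M[i, i], M[j, j], M[i, j]
        phi = 0.5 * np.arctan2(a - b, 2 * c2)
        G = np.eye(p)
        G[i, i] = G[j, j] = np.cos(phi)
        G[i, j], G[j, i] = -np.sin(phi), np.sin(phi)
        Q = G @ Q
    return E @ np.diag(np.sqrt(n * eigs)) @ Q.T


def make_fixture_suite(seed: int = 0) -> dict[str, GeneratedSession]:
    """Three canonical fixtures used across the test suite.

    tiny: 50 trials x 20 units; medium: 500 x 60; null: no swaps/guesses
    (p_swap = p_guess ~ 0).  Fully determined by ``seed``.
    """
    fixtures = {}
    tiny = GeneratorSpec(n_sessions=1, trials_per_session=50, n_units=20, seed=seed)
    fixtures["tiny"] = generate_session(tiny, np.random.default_rng(seed), 0)
    medium = GeneratorSpec(n_sessions=1, trials_per_session=500, n_units=60, seed=seed + 1)
    fixtures["medium"] = generate_session(medium, np.random.default_rng(seed + 1), 0)
    null = GeneratorSpec(
        n_sessions=1, trials_per_session=200, n_units=20,
        w_swap=-30.0, w_guess=-30.0, s_swap=1e-6, s_guess=1e-6, seed=seed + 2,
    )
    fixtures["null"] = generate_session(null, np.random.default_rng(seed + 2), 0)
    return fixtures
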