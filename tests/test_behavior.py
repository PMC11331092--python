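"""Behavioral mixture model: density, transforms, posteriors, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from swapmix.behavior import (
    HierarchicalBehaviorModel,
    SessionBehaviorParams,
    logits_to_probs,
    posterior_predictive,
    response_log_density,
    type_posteriors_from_params,
)
from swapmix.circular import circ_dist, wrapped_normal_pdf
from swapmix.synth import GeneratorSpec, generate_study


def test_logit_transform_closed_forms():
    np.testing.assert_allclose(logits_to_probs(0.0, 0.0), [1 / 3] * 3)
    p_s, p_g, p_c = logits_to_probs(np.log(2.0), 0.0)
    np.testing.assert_allclose([p_s, p_g, p_c], [0.5, 0.25, 0.25])
    assert logits_to_probs(-30.0, -30.0)[2] == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        logits_to_probs(np.inf, 0.0)


def test_guess_component_density_is_uniform():
    params = SessionBehaviorParams(p_swap=0.0, p_guess=1.0, sigma=0.5)
    for report in np.linspace(0, 2 * np.pi, 17, endpoint=False):
        assert response_log_density(report, 1.0, 4.0, params) == pytest.approx(
            np.log(1 / (2 * np.pi))
        )


def test_density_at_target_matches_wrap_sum_oracle():
    params = SessionBehaviorParams(p_swap=0.0, p_guess=0.0, sigma=0.5)
    dens = np.exp(response_log_density(1.0, 1.0, 4.0, params))
    # wrap-sum oracle at the mode: k=0 term dominates, correction < 1e-30
    oracle = sum(
        np.exp(-0.5 * (2 * np.pi * k / 0.5) ** 2) for k in range(-3, 4)
    ) / (np.sqrt(2 * np.pi) * 0.5)
    assert dens == pytest.approx(oracle, rel=1e-12)
    assert dens == pytest.approx(0.7978845608, abs=1e-9)


def test_coincident_components_reduce_to_single_wrapped_normal():
    pa = SessionBehaviorParams(p_swap=0.7, p_guess=0.0, sigma=0.4)
    pb = SessionBehaviorParams(p_swap=0.1, p_guess=0.0, sigma=0.4)
    r = np.linspace(0, 2 * np.pi, 9)
    np.testing.assert_allclose(
        response_log_density(r, 2.0, 2.0, pa), response_log_density(r, 2.0, 2.0, pb)
    )


@pytest.mark.parametrize("params", [
    SessionBehaviorParams(0.1, 0.2, 0.3),
    SessionBehaviorParams(0.4, 0.4, 0.9),
    SessionBehaviorParams(0.0, 0.05, 0.15),
])
def test_mixture_density_integrates_to_one(params):
    total = quad(
        lambda r: np.exp(response_log_density(r, 1.0, 3.5, params)),
        0, 2 * np.pi, limit=200,
    )[0]
    assert total == pytest.approx(1.0, abs=1e-6)


class TestTrialTypePosteriors:
    def test_zero_swap_prior_zeroes_swap_posterior(self):
        trials = pd.DataFrame({"session_id": "s0", "c_report": [0.3, 2.0],
                               "t": [0.3, 0.3], "d": [2.0, 2.0]})
        params = SessionBehaviorParams(p_swap=0.0, p_guess=0.3, sigma=0.4)
        post = type_posteriors_from_params(trials, params)
        np.testing.assert_allclose(post["p_swap_post"], 0.0)

    def test_report_at_distant_distractor_is_classified_swap(self):
        trials = pd.DataFrame({"session_id": "s0", "c_report": [1.0 + np.pi],
                               "t": [1.0], "d": [1.0 + np.pi]})
        params = SessionBehaviorParams(p_swap=0.3, p_guess=0.1, sigma=0.2)
        post = type_posteriors_from_params(trials, params)
        # direct Bayes-rule oracle
        f_t = float(wrapped_normal_pdf(np.array([np.pi]), np.array([0.2]))[0])
        f_d = float(wrapped_normal_pdf(np.array([0.0]), np.array([0.2]))[0])
        expect = 0.3 * f_d / (0.6 * f_t + 0.3 * f_d + 0.1 / (2 * np.pi))
        assert post["p_swap_post"].iloc[0] == pytest.approx(expect, abs=1e-12)
        assert post["p_swap_post"].iloc[0] > 0.95

    def test_flat_likelihood_limit_gives_equal_posteriors(self):
        trials = pd.DataFrame({"session_id": "s0", "c_report": [0.7],
                               "t": [1.0], "d": [4.0]})
        params = SessionBehaviorParams(p_swap=1 / 3, p_guess=1 / 3, sigma=50.0)
        post = type_posteriors_from_params(trials, params)
        np.testing.assert_allclose(post.iloc[0], 1 / 3, atol=1e-3)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        trials = pd.DataFrame({
            "session_id": "s0", "c_report": rng.uniform(0, 2 * np.pi, 50),
            "t": rng.uniform(0, 2 * np.pi, 50), "d": rng.uniform(0, 2 * np.pi, 50),
        })
        post = type_posteriors_from_params(trials, SessionBehaviorParams(0.2, 0.1, 0.35))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestPosteriorPredictive:
    def _trials(self, n):
        rng = np.random.default_rng(1)
        return pd.DataFrame({
            "session_id": "s0", "u": rng.uniform(0, 2 * np.pi, n),
            "l": rng.uniform(0, 2 * np.pi, n), "c": rng.integers(0, 2, n),
        })

    def test_pure_guess_samples_are_uniform(self):
        trials = self._trials(5000)
        sim = posterior_predictive(
            SessionBehaviorParams(0.0, 1.0, 0.4), trials, np.random.default_rng(2)
        )
        assert kstest(sim, "uniform", args=(0, 2 * np.pi)).pvalue > 0.01

    def test_pure_correct_errors_match_wrapped_normal_moments(self):
        trials = self._trials(5000)
        sim = posterior_predictive(
            SessionBehaviorParams(0.0, 0.0, 0.4), trials, np.random.default_rng(3)
        )
        from swapmix.data_model import derive_target_distractor

        t = derive_target_distractor(trials)["t"].to_numpy()
        err = circ_dist(sim, t)
        assert abs(err.mean()) < 3 * 0.4 / np.sqrt(5000)
        assert err.std() == pytest.approx(0.4, abs=0.02)

    def test_seeded_determinism(self):
        trials = self._trials(100)
        p = SessionBehaviorParams(0.2, 0.1, 0.35)
        a = posterior_predictive(p, trials, np.random.default_rng(7))
        b = posterior_predictive(p, trials, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestFitting:
    def test_map_fit_on_degenerate_data_finds_pure_correct(self):
        rng = np.random.default_rng(4)
        n = 300
        u = rng.uniform(0, 2 * np.pi, n)
        l = rng.uniform(0, 2 * np.pi, n)
        c = rng.integers(0, 2, n)
        t = np.where(c == 1, u, l)
        trials = pd.DataFrame({
            "session_id": "s0", "trial_id": range(n), "task_type": "retro",
            "u": u, "l": l, "c": c,
            "c_report": np.mod(t + 0.1 * rng.normal(size=n), 2 * np.pi),
            "response_time": np.nan,
        })
        model = HierarchicalBehaviorModel(method="map").fit(trials)
        assert model.session_params_[0].p_correct > 0.95
        assert model.session_params_[0].sigma == pytest.approx(0.1, abs=0.03)

    def test_fit_invariant_to_global_color_rotation(self):
        spec = GeneratorSpec(n_sessions=2, trials_per_session=200, seed=11)
        trials, _ = generate_study(spec)
        m1 = HierarchicalBehaviorModel(method="map").fit(trials)
        rotated = trials.copy()
        for col in ("u", "l", "c_report", "t", "d"):
            rotated[col] = np.mod(rotated[col] + 1.2345, 2 * np.pi)
        m2 = HierarchicalBehaviorModel(method="map").fit(rotated)
        for a, b in zip(m1.session_params_, m2.session_params_):
            assert a.p_swap == pytest.approx(b.p_swap, abs=1e-6)
            assert a.sigma == pytest.approx(b.sigma, abs=1e-6)

    def test_hierarchical_pooling_shrinks_session_estimates(self):
        # common truth across sessions: pooled posterior means vary less
        # than independent per-session fits
        spec = GeneratorSpec(n_sessions=6, trials_per_session=150,
                             s_swap=1e-6, s_guess=1e-6, seed=12)
        trials, _ = generate_study(spec)
        pooled = HierarchicalBehaviorModel(chains=2, warmup=300, samples=300,
                                           seed=1).fit(trials)
        pooled_sd = np.std([p.p_swap for p in pooled.session_params_])
        indep = []
        for sid, sub in trials.groupby("session_id"):
            m = HierarchicalBehaviorModel(method="map").fit(sub)
            indep.append(m.session_params_[0].p_swap)
        assert pooled_sd < 0.5 * np.std(indep)

    def test_short_mcmc_chain_recovers_and_diagnoses(self):
        spec = GeneratorSpec(n_sessions=2, trials_per_session=250, seed=13)
        trials, sessions = generate_study(spec)
        model = HierarchicalBehaviorModel(chains=2, warmup=400, samples=400,
                                          seed=1).fit(trials)
        assert model.diagnostics_["max_rhat"] < 1.1
        for est, ses in zip(model.session_params_, sessions):
            assert est.p_swap == pytest.approx(ses.truth.params.p_swap, abs=0.08)
        # draw-averaged and plug-in posteriors agree closely on these data
        pa = model.predict_proba(trials, draw_averaged=True)
        pb = model.predict_proba(trials, draw_averaged=False)
        assert np.abs(pa.to_numpy() - pb.to_numpy()).max() < 0.05

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            HierarchicalBehaviorModel(method="map").fit(
                pd.DataFrame(columns=["session_id", "c_report", "t", "d"])
            )

    def test_estimator_params_round_trip(self):
        m = HierarchicalBehaviorModel(chains=2)
        params = m.get_params()
        assert params["chains"] == 2
        m.set_params(chains=6)
        assert m.chains == 6
        with pytest.raises(ValueError):
            m.set_params(bogus=1)
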