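"""Spline encoding models: designs, ridge fits, hypothesis prototypes."""

import numpy as np
import pandas as pd
import pytest

from swapmix.data_model import TrialRecord
from swapmix.encoders import (
    Delay1Encoder,
    Delay2Encoder,
    SplineEncoderRegression,
    delay2_design,
    fit_encoder_ridge,
    make_prototype,
    predict_delay1,
    predict_delay2,
)
from swapmix.splines import SplineBasisSpec, spline_basis


def _rand_encoder1(rng, dims=6, K=5):
    basis = SplineBasisSpec(K, 1)
    return Delay1Encoder(rng.normal(size=(dims, K)), rng.normal(size=(dims, K)),
                         np.ones(dims), basis)


def _rand_encoder2(rng, dims=6, K=5):
    basis = SplineBasisSpec(K, 1)
    return Delay2Encoder(*(rng.normal(size=(dims, K)) for _ in range(4)),
                         rng.normal(size=dims), rng.normal(size=dims),
                         np.ones(dims), basis)


def _trials(rng, n, cue=None):
    c = rng.integers(0, 2, n) if cue is None else np.full(n, cue)
    return pd.DataFrame({
        "session_id": "s0", "trial_id": range(n), "task_type": "retro",
        "u": rng.uniform(0, 2 * np.pi, n), "l": rng.uniform(0, 2 * np.pi, n),
        "c": c, "c_report": rng.uniform(0, 2 * np.pi, n), "response_time": np.nan,
    })


def test_delay1_prediction_ignores_zeroed_color_weights():
    rng = np.random.default_rng(0)
    enc = _rand_encoder1(rng)
    enc.W_l[:] = 0.0
    p1 = predict_delay1(enc, np.array([1.0, 1.0]), np.array([0.3, 5.0]))
    np.testing.assert_allclose(p1[0], p1[1])


def test_delay1_prediction_is_additive_in_the_two_colors():
    rng = np.random.default_rng(1)
    enc = _rand_encoder1(rng)
    zero_l = Delay1Encoder(enc.W_u, np.zeros_like(enc.W_l), enc.sigma, enc.basis)
    zero_u = Delay1Encoder(np.zeros_like(enc.W_u), enc.W_l, enc.sigma, enc.basis)
    u, l = np.array([0.7]), np.array([4.0])
    np.testing.assert_allclose(
        predict_delay1(enc, u, l),
        predict_delay1(zero_l, u, l) + predict_delay1(zero_u, u, l),
        atol=1e-12,
    )


def test_delay2_matches_bruteforce_basis_expansion():
    rng = np.random.default_rng(2)
    enc = _rand_encoder2(rng)
    for _ in range(100):
        u, l = rng.uniform(0, 2 * np.pi, 2)
        c = int(rng.integers(0, 2))
        fu, fl = spline_basis(u, enc.basis), spline_basis(l, enc.basis)
        if c == 1:
            expect = enc.W_ut @ fu + enc.W_ld @ fl + enc.b_1
        else:
            expect = enc.W_lt @ fl + enc.W_ud @ fu + enc.b_0
        got = predict_delay2(enc, np.array([u]), np.array([l]), np.array([c]))[0]
        np.testing.assert_allclose(got, expect, atol=1e-12)


def test_delay2_intercept_only_model_predicts_intercepts():
    rng = np.random.default_rng(3)
    enc = _rand_encoder2(rng)
    for name in ("W_ut", "W_ud", "W_lt", "W_ld"):
        getattr(enc, name)[:] = 0.0
    got1 = predict_delay2(enc, np.array([1.0]), np.array([2.0]), np.array([1]))[0]
    got0 = predict_delay2(enc, np.array([1.0]), np.array([2.0]), np.array([0]))[0]
    np.testing.assert_allclose(got1, enc.b_1)
    np.testing.assert_allclose(got0, enc.b_0)


def test_delay2_rejects_nonbinary_cue():
    rng = np.random.default_rng(4)
    enc = _rand_encoder2(rng)
    with pytest.raises(ValueError):
        predict_delay2(enc, np.array([1.0]), np.array([2.0]), np.array([2]))


class TestRidgeFit:
    def test_noiseless_delay1_weights_recovered(self):
        rng = np.random.default_rng(5)
        true = _rand_encoder1(rng, dims=8)
        trials = _trials(rng, 500)
        activity = predict_delay1(true, trials["u"].to_numpy(), trials["l"].to_numpy())
        fit = fit_encoder_ridge(activity, trials, epoch="delay1", alpha=1e-8)
        pred = predict_delay1(fit, trials["u"].to_numpy(), trials["l"].to_numpy())
        assert np.abs(pred - activity).max() < 1e-6
        assert fit.sigma.max() < 1e-6

    def test_noiseless_delay2_predictions_recovered(self):
        rng = np.random.default_rng(6)
        true = _rand_encoder2(rng, dims=8)
        trials = _trials(rng, 600)
        activity = predict_delay2(true, trials["u"].to_numpy(),
                                  trials["l"].to_numpy(), trials["c"].to_numpy())
        fit = fit_encoder_ridge(activity, trials, epoch="delay2", alpha=1e-8)
        pred = predict_delay2(fit, trials["u"].to_numpy(), trials["l"].to_numpy(),
                              trials["c"].to_numpy())
        assert np.abs(pred - activity).max() < 1e-6

    def test_infinite_ridge_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(7)
        true = _rand_encoder1(rng)
        trials = _trials(rng, 100)
        activity = predict_delay1(true, trials["u"].to_numpy(), trials["l"].to_numpy())
        fit = fit_encoder_ridge(activity, trials, epoch="delay1", alpha=1e12)
        assert np.abs(fit.theta).max() < 1e-6

    def test_single_cue_training_set_warns(self):
        rng = np.random.default_rng(8)
        trials = _trials(rng, 80, cue=1)
        activity = rng.normal(size=(80, 5))
        with pytest.warns(UserWarning, match="cue"):
            fit_encoder_ridge(activity, trials, epoch="delay2")

    def test_fit_equivariant_to_global_color_rotation(self):
        rng = np.random.default_rng(9)
        true = _rand_encoder1(rng)
        trials = _trials(rng, 400)
        activity = predict_delay1(true, trials["u"].to_numpy(), trials["l"].to_numpy())
        fit = fit_encoder_ridge(activity, trials, epoch="delay1", alpha=1e-6)
        shift = 2 * np.pi / 5  # one knot spacing: design permutes exactly
        rotated = trials.copy()
        rotated["u"] = np.mod(rotated["u"] + shift, 2 * np.pi)
        rotated["l"] = np.mod(rotated["l"] + shift, 2 * np.pi)
        fit_rot = fit_encoder_ridge(activity, rotated, epoch="delay1", alpha=1e-6)
        pred = predict_delay1(fit, trials["u"].to_numpy()[:10], trials["l"].to_numpy()[:10])
        pred_rot = predict_delay1(fit_rot, np.mod(trials["u"].to_numpy()[:10] + shift, 2 * np.pi),
                                  np.mod(trials["l"].to_numpy()[:10] + shift, 2 * np.pi))
        np.testing.assert_allclose(pred, pred_rot, atol=1e-6)


class TestPrototypes:
    def _trial(self, u=0.5, l=2.0, c=1, rep=0.6):
        return TrialRecord(trial_id=0, task_type="retro", u=u, l=l, c=c, c_report=rep)

    def test_nominal_prototype_equals_model_prediction(self):
        rng = np.random.default_rng(10)
        enc = _rand_encoder2(rng)
        tr = self._trial()
        proto = make_prototype(enc, tr, "nominal")
        np.testing.assert_allclose(
            proto.mean,
            predict_delay2(enc, np.array([tr.u]), np.array([tr.l]), np.array([tr.c]))[0],
        )

    def test_misbound_with_equal_colors_is_nominal(self):
        rng = np.random.default_rng(11)
        enc = _rand_encoder1(rng)
        tr = self._trial(u=1.0, l=1.0)
        np.testing.assert_allclose(
            make_prototype(enc, tr, "misbound").mean,
            make_prototype(enc, tr, "nominal").mean,
        )

    def test_misinterpreted_cue_is_an_involution(self):
        rng = np.random.default_rng(12)
        enc = _rand_encoder2(rng)
        for _ in range(50):
            tr = self._trial(u=rng.uniform(0, 2 * np.pi), l=rng.uniform(0, 2 * np.pi),
                             c=int(rng.integers(0, 2)))
            once = make_prototype(enc, tr, "misinterpreted_cue")
            u2, l2, c2 = once.condition
            twice = make_prototype(
                enc, TrialRecord(0, "retro", u2, l2, int(c2), tr.c_report),
                "misinterpreted_cue",
            )
            np.testing.assert_allclose(
                twice.mean, make_prototype(enc, tr, "nominal").mean, atol=1e-12
            )

    def test_reported_guess_requires_report(self):
        rng = np.random.default_rng(13)
        enc = _rand_encoder2(rng)
        tr = self._trial()
        tr.c_report = None
        with pytest.raises(ValueError):
            make_prototype(enc, tr, "reported_guess")

    def test_misinterpreted_cue_rejected_for_delay1(self):
        rng = np.random.default_rng(14)
        enc = _rand_encoder1(rng)
        with pytest.raises(ValueError):
            make_prototype(enc, self._trial(), "misinterpreted_cue")


def test_estimator_wrapper_fits_and_scores():
    rng = np.random.default_rng(15)
    true = _rand_encoder2(rng, dims=5)
    trials = _trials(rng, 300)
    activity = predict_delay2(true, trials["u"].to_numpy(), trials["l"].to_numpy(),
                              trials["c"].to_numpy())
    est = SplineEncoderRegression(epoch="delay2", alpha=1e-8).fit(trials, activity)
    assert est.score(trials, activity) > 0.999
    assert est.predict(trials).shape == activity.shape


def test_single_stimulus_design_zeroes_missing_color():
    basis = SplineBasisSpec(5, 1)
    X = delay2_design(np.array([np.nan]), np.array([2.0]), np.array([0]), basis)
    assert np.all(X[0, 5:10] == 0)  # W_ud block empty
    assert X[0, 10:15].sum() == pytest.approx(1.0)  # W_lt block active
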