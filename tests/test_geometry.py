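"""Projection index, cross-validated distances, and the MDS embedding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swapmix.geometry import (
    CVDistanceMatrix,
    average_distance_matrices,
    cv_squared_distance,
    loo_projection_analysis,
    mds_embed,
    projection_index,
    session_distance_matrix,
    window_starts,
)
from swapmix.synth import GeneratorSpec, generate_session
from swapmix.behavior import type_posteriors_from_params


class TestProjectionIndex:
    def test_anchors(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert projection_index(b, a, b) == 0.0
        assert projection_index(a, a, b) == 1.0
        mid = (a + b) / 2
        assert projection_index(mid, a, b) == pytest.approx(0.5)

    def test_orthogonal_displacement_is_invisible(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(size=6)
        axis = a - b
        v = rng.normal(size=6)
        v -= (v @ axis) / (axis @ axis) * axis
        r = rng.normal(size=6)
        assert projection_index(r + 3 * v, a, b) == pytest.approx(
            projection_index(r, a, b), abs=1e-12
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_joint_orthogonal_transform(self, seed):
        rng = np.random.default_rng(seed)
        a, b, r = (rng.normal(size=5) for _ in range(3))
        if np.linalg.norm(a - b) < 1e-6:
            return
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert projection_index(Q @ r, Q @ a, Q @ b) == pytest.approx(
            projection_index(r, a, b), abs=1e-9
        )

    def test_coincident_prototypes_rejected(self):
        v = np.ones(4)
        with pytest.raises(ValueError):
            projection_index(v, v, v)

    def test_unanchored_variant_differs_by_offset_only(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=5), rng.normal(size=5)
        r1, r2 = rng.normal(size=5), rng.normal(size=5)
        d_anch = projection_index(r1, a, b) - projection_index(r2, a, b)
        d_raw = (projection_index(r1, a, b, anchored=False)
                 - projection_index(r2, a, b, anchored=False))
        assert d_anch == pytest.approx(d_raw, abs=1e-12)


def test_window_bookkeeping_arithmetic():
    starts = window_starts(0.0, 2.0, width=0.5, step=0.25)
    assert len(starts) == int(np.floor((2.0 - 0.5) / 0.25)) + 1
    with pytest.raises(ValueError):
        window_starts(0.0, 0.3, width=0.5, step=0.25)


class TestLOOProjection:
    def _setup(self, mechanism, seed, p_resp=0.0):
        spec = GeneratorSpec(n_sessions=1, trials_per_session=250, n_units=30,
                             seed=seed, mechanism_mix={mechanism: 1.0},
                             p_resp_true=p_resp, noise_sd=0.3,
                             target_separation=None, weight_scale=0.5)
        ses = generate_session(spec, np.random.default_rng(seed), 0)
        behav = type_posteriors_from_params(ses.trials, ses.truth.params)
        act = ses.epochs["delay2"].summed().astype(float)
        return ses, behav, act

    def test_injected_misselection_separates_classes(self):
        ses, behav, act = self._setup("misselect", 51)
        summ = loo_projection_analysis(
            act, ses.trials, behav, epoch="delay2",
            hypothesis_pair=("misselected_colors", "nominal"), seed=0, n_boot=200)
        assert summ.difference > 0.5
        assert summ.ci_low > 0

    def test_close_color_trials_are_excluded(self):
        ses, behav, act = self._setup("misselect", 52)
        summ = loo_projection_analysis(
            act, ses.trials, behav, epoch="delay2",
            hypothesis_pair=("misselected_colors", "nominal"), seed=0, n_boot=50)
        from swapmix.circular import circ_dist

        sep = np.abs(circ_dist(ses.trials["u"].to_numpy(), ses.trials["l"].to_numpy()))
        ok = sep >= np.pi / 4
        correct = behav["p_correct_post"].to_numpy() > 0.3
        assert len(summ.x_correct) == int((ok & correct).sum())

    def test_insufficient_correct_trials_raise(self):
        ses, behav, act = self._setup("misselect", 53)
        starved = behav.copy()
        starved["p_correct_post"] = 0.0
        with pytest.raises(ValueError, match="likely-correct"):
            loo_projection_analysis(act, ses.trials, starved, epoch="delay2",
                                    hypothesis_pair=("misselected_colors", "nominal"))

    def test_leave_one_out_integrity(self):
        ses, behav, act = self._setup("misselect", 54)
        kwargs = dict(epoch="delay2",
                      hypothesis_pair=("misselected_colors", "nominal"),
                      seed=0, n_boot=10)
        summ = loo_projection_analysis(act, ses.trials, behav, **kwargs)
        correct = np.where(behav["p_correct_post"].to_numpy() > 0.3)[0]
        from swapmix.circular import circ_dist

        sep = np.abs(circ_dist(ses.trials["u"].to_numpy(), ses.trials["l"].to_numpy()))
        correct = [i for i in correct if sep[i] >= np.pi / 4]
        swap = np.where((behav["p_swap_post"].to_numpy() > 0.3)
                        & (sep >= np.pi / 4))[0]

        # (a) swap trials never enter any training set: perturbing one leaves
        # every correct trial's x bit-identical
        act_s = act.copy()
        act_s[swap[0]] *= 5.0
        summ_s = loo_projection_analysis(act_s, ses.trials, behav, **kwargs)
        np.testing.assert_array_equal(summ.x_correct, summ_s.x_correct)

        # (b) the held-out trial does not shape its own fold's encoder or
        # prototypes, so its x responds exactly linearly to a perturbation
        rng = np.random.default_rng(0)
        delta = rng.normal(size=act.shape[1])
        act_1 = act.copy(); act_1[correct[0]] += delta
        act_2 = act.copy(); act_2[correct[0]] += 2 * delta
        x0 = summ.x_correct[0]
        x1 = loo_projection_analysis(act_1, ses.trials, behav, **kwargs).x_correct[0]
        x2 = loo_projection_analysis(act_2, ses.trials, behav, **kwargs).x_correct[0]
        assert abs(x1 - x0) > 1e-6
        assert x2 - x0 == pytest.approx(2 * (x1 - x0), rel=1e-9)


class TestCVDistance:
    def _frame(self, n):
        return pd.DataFrame({"u": 0.1, "l": 2.0, "c": 1, "c_report": 0.1,
                             "task_type": "retro", "session_id": "s0",
                             "trial_id": range(n)})

    def test_noiseless_separation_two_gives_every_estimate_four(self):
        n = 10
        mu_b = np.zeros(6)
        mu_b[0] = 2.0
        act = np.vstack([np.zeros((n, 6)), np.tile(mu_b, (n, 1))])
        est, mean, se = cv_squared_distance(
            act, self._frame(2 * n), idx_a=np.arange(n), idx_b=np.arange(n, 2 * n))
        assert len(est) == n * n
        np.testing.assert_allclose(est, 4.0, atol=1e-12)

    def test_same_mean_unbiased_over_replicates(self):
        rng = np.random.default_rng(3)
        frame = self._frame(12)
        means = []
        for _ in range(100):
            act = rng.normal(size=(12, 6))
            _, mean, _ = cv_squared_distance(
                act, frame, idx_a=np.arange(6), idx_b=np.arange(6, 12))
            means.append(mean)
        means = np.asarray(means)
        assert abs(means.mean()) < 2 * means.std(ddof=1) / np.sqrt(len(means))

    def test_variance_shrinks_with_reference_set_size(self):
        rng = np.random.default_rng(4)
        sds = []
        for n in (4, 16, 64):
            frame = self._frame(2 * n)
            reps = []
            for _ in range(40):
                act = rng.normal(size=(2 * n, 5))
                _, mean, _ = cv_squared_distance(
                    act, frame, idx_a=np.arange(n), idx_b=np.arange(n, 2 * n))
                reps.append(mean)
            sds.append(np.std(reps))
        assert sds[0] > sds[1] > sds[2]


class TestDistanceMatrix:
    def test_matrix_symmetry_and_zero_diagonal(self, small_session):
        ses = small_session
        behav = type_posteriors_from_params(ses.trials, ses.truth.params)
        act = ses.epochs["delay2"].summed().astype(float)
        mat = session_distance_matrix(act, ses.trials, behav, n_color_bins=4)
        np.testing.assert_array_equal(mat.matrix, mat.matrix.T)
        np.testing.assert_array_equal(np.diag(mat.matrix), 0.0)

    def test_coincident_representations_give_near_zero_cell(self):
        # all-cue-1 world where flipping the cue changes nothing: build
        # activity that depends only on colors
        rng = np.random.default_rng(5)
        n = 120
        u = rng.uniform(0, 2 * np.pi, n)
        l = rng.uniform(0, 2 * np.pi, n)
        trials = pd.DataFrame({"u": u, "l": l, "c": rng.integers(0, 2, n),
                               "c_report": u, "task_type": "retro",
                               "session_id": "s0", "trial_id": range(n)})
        act = np.column_stack([np.cos(u), np.sin(u), np.cos(l), np.sin(l)])
        act = act + 0.05 * rng.normal(size=act.shape)
        behav = pd.DataFrame({"p_correct_post": np.ones(n),
                              "p_swap_post": np.zeros(n),
                              "p_guess_post": np.zeros(n)})
        mat = session_distance_matrix(act, trials, behav, n_color_bins=4)
        # nominal vs misinterpreted-cue: cue plays no role here -> ~0
        i, j = 0, 2
        assert abs(mat.matrix[i, j]) < 0.1 * abs(mat.matrix[0, 1])

    def test_average_matrices_simple_mean(self):
        m1 = CVDistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float),
                              np.zeros((3, 3)), np.ones((3, 3), int))
        m2 = CVDistanceMatrix(("a", "b", "c"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                              np.zeros((3, 3)), np.ones((3, 3), int))
        avg = average_distance_matrices([m1, m2])
        assert avg.matrix[0, 1] == pytest.approx(2.0)
        assert avg.matrix[1, 2] == pytest.approx(4.0)


class TestMDS:
    def test_equilateral_triangle(self):
        X = mds_embed(np.ones((3, 3)) - np.eye(3))
        d = np.linalg.norm(X[:, None] - X[None], axis=-1)
        np.testing.assert_allclose(d + np.eye(3), np.ones((3, 3)), atol=1e-9)

    def test_degenerate_all_zero(self):
        X = mds_embed(np.zeros((3, 3)))
        np.testing.assert_allclose(X, 0.0, atol=1e-12)

    def test_3_4_5_right_triangle(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        X = mds_embed(D)
        rec = np.linalg.norm(X[:, None] - X[None], axis=-1)
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_squared_estimates_are_rooted_and_floored(self):
        mat = CVDistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 4.0, 2.25], [4.0, 0, 1.0], [2.25, 1.0, 0]]),
            np.zeros((3, 3)), np.ones((3, 3), int),
        )
        np.testing.assert_allclose(
            mat.rooted(), np.sqrt(np.clip(mat.matrix, 0, None))
        )
        X = mds_embed(mat)  # metric distances (2, 1.5, 1): exact embedding
        rec = np.linalg.norm(X[:, None] - X[None], axis=-1)
        np.testing.assert_allclose(rec, mat.rooted(), atol=1e-9)

    def test_negative_cell_floored_with_distortion_warning(self):
        mat = CVDistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 4.0, -0.5], [4.0, 0, 1.0], [-0.5, 1.0, 0]]),
            np.zeros((3, 3)), np.ones((3, 3), int),
        )
        assert mat.rooted()[0, 2] == 0.0
        with pytest.warns(UserWarning, match="triangle"):
            mds_embed(mat)
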