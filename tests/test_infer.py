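"""Forward/backward inference against linear-Gaussian oracles."""

import numpy as np
import pytest
import scipy.linalg

import oracles
from navinfer import infer
from navinfer.infer import (
    AgentTransition,
    Belief,
    ControlEstimate,
    LinearObservation,
    LinearTransition,
    backward_smooth,
    correct_step,
    forward_filter,
    infer_inputs,
    predict_step,
    sequence_loglik,
)


def random_lds(rng, n=3, m=2, stable=0.95):
    A = rng.normal(0, 1, (n, n))
    A *= stable / max(np.abs(np.linalg.eigvals(A)))
    B = rng.normal(0, 1, (n, 1))
    H = rng.normal(0, 1, (m, n))
    Q = 0.05 * np.eye(n)
    R = 0.1 * np.eye(m)
    return A, B, H, Q, R


def simulate_lds(rng, A, B, H, Q, R, T):
    n = A.shape[0]
    x = rng.normal(0, 1, n)
    controls = rng.normal(0, 1, (T, B.shape[1]))
    ys = []
    for t in range(T):
        x = A @ x + B @ controls[t] + rng.multivariate_normal(np.zeros(n), Q)
        ys.append(H @ x + rng.multivariate_normal(np.zeros(H.shape[0]), R))
    return controls, np.array(ys)


class TestPredictStep:
    def test_zero_noise_zero_cov(self):
        tr = LinearTransition(np.eye(2), np.zeros((2, 1)), np.zeros((2, 2)))
        pred = predict_step(Belief(np.ones(2), np.zeros((2, 2))), tr, [0.0])
        assert np.allclose(pred.mean, 1.0)
        assert np.allclose(pred.cov, 0.0)

    def test_random_walk_adds_q(self):
        tr = LinearTransition(np.eye(2), np.zeros((2, 1)), 0.3 * np.eye(2))
        pred = predict_step(Belief(np.zeros(2), 0.5 * np.eye(2)), tr, [0.0])
        assert np.allclose(pred.cov, 0.8 * np.eye(2))

    def test_nonlinear_mean_propagation(self):
        tr = AgentTransition(dt=0.05, k=1.0, Q=np.zeros((4, 4)))
        b = Belief(np.array([0.1, 0.2, 0.5, 0.7]), 1e-3 * np.eye(4))
        pred = predict_step(b, tr, [0.2, 0.1])
        from navinfer.dynamics import step

        assert np.allclose(pred.mean, step(b.mean, [0.2, 0.1], dt=0.05))


class TestCorrectStep:
    def test_scalar_textbook_fusion(self):
        # prior variance 1, identity observation, noise variance 1 -> K = 1/2
        pred = infer.Prediction(mean=np.zeros(1), cov=np.eye(1), flow=np.eye(1))
        obs_model = LinearObservation(np.eye(1), np.eye(1))
        belief, ll = correct_step(pred, np.array([1.0]), obs_model)
        assert belief.mean[0] == pytest.approx(0.5)
        assert belief.cov[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_uninformative_observation_keeps_prediction(self):
        pred = infer.Prediction(mean=np.array([0.3, -0.2]), cov=0.1 * np.eye(2), flow=np.eye(2))
        obs_model = LinearObservation(np.eye(2), 1e12 * np.eye(2))
        belief, _ = correct_step(pred, np.array([100.0, -50.0]), obs_model)
        assert np.allclose(belief.mean, pred.mean, atol=1e-6)

    def test_exact_observation_solves_linear_system(self, rng):
        G = rng.normal(0, 1, (2, 2))
        pred = infer.Prediction(mean=rng.normal(0, 1, 2), cov=np.eye(2), flow=np.eye(2))
        obs_model = LinearObservation(G, 1e-14 * np.eye(2))
        y = rng.normal(0, 1, 2)
        belief, _ = correct_step(pred, y, obs_model)
        # with square invertible G and vanishing noise the posterior mean
        # satisfies the linearised observation equation
        assert np.allclose(G @ belief.mean, y, atol=1e-4)


class TestForwardFilterOracle:
    def test_matches_reference_kalman_filter(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A, B, H, Q, R = random_lds(rng)
            controls, ys = simulate_lds(rng, A, B, H, Q, R, 50)
            prior = Belief(np.zeros(3), np.eye(3))
            res = forward_filter(LinearTransition(A, B, Q), LinearObservation(H, R), prior, controls, ys)
            ms, Ps, pm, pP, ll = oracles.kalman_filter(A, B, H, Q, R, np.zeros(3), np.eye(3), controls, ys)
            assert np.allclose(res.filtered_means, ms, atol=1e-8)
            assert np.allclose(res.filtered_covs, Ps, atol=1e-8)
            assert res.loglik == pytest.approx(ll, abs=1e-6)

    def test_lesion_covariance_never_shrinks(self, mini_model):
        # the agent's path integrator accrues uncertainty monotonically
        # when the correction step is removed
        rng = np.random.default_rng(0)
        tr = AgentTransition(Q=1e-4 * np.eye(4))
        prior = Belief(np.array([0.5, 0.5, 0.1, 0.3]), 1e-10 * np.eye(4))
        controls = rng.normal(0, 0.2, (60, 2))
        obs = np.zeros((60, mini_model.n_channels))
        res = forward_filter(tr, mini_model, prior, controls, obs, lesion=True)
        traces = [np.trace(b.cov) for b in res.beliefs]
        assert all(b >= a - 1e-12 for a, b in zip(traces, traces[1:]))

    def test_lesion_is_pure_path_integration(self, toy_lds):
        d = toy_lds
        prior = Belief(d["x0_mean"], d["x0_cov"])
        res = forward_filter(
            LinearTransition(d["A"], d["B"], d["Q"]),
            LinearObservation(d["H"], d["R"]),
            prior,
            d["controls"],
            d["observations"],
            lesion=True,
        )
        x = d["x0_mean"]
        for t, b in enumerate(res.beliefs[1:]):
            x = d["A"] @ x + d["B"] @ d["controls"][t]
            assert np.allclose(b.mean, x, atol=1e-12)

    def test_mismatched_lengths_rejected(self, toy_lds):
        d = toy_lds
        with pytest.raises(ValueError):
            forward_filter(
                LinearTransition(d["A"], d["B"], d["Q"]),
                LinearObservation(d["H"], d["R"]),
                Belief(d["x0_mean"], d["x0_cov"]),
                d["controls"][:10],
                d["observations"],
            )

    def test_covariances_stay_psd(self, toy_lds):
        d = toy_lds
        res = forward_filter(
            LinearTransition(d["A"], d["B"], d["Q"]),
            LinearObservation(d["H"], d["R"]),
            Belief(d["x0_mean"], d["x0_cov"]),
            d["controls"],
            d["observations"],
        )
        for b in res.beliefs:
            assert np.min(np.linalg.eigvalsh(b.cov)) >= -1e-10


class TestSequenceLoglik:
    def test_total_equals_sum_of_increments(self, toy_lds):
        d = toy_lds
        res = forward_filter(
            LinearTransition(d["A"], d["B"], d["Q"]),
            LinearObservation(d["H"], d["R"]),
            Belief(d["x0_mean"], d["x0_cov"]),
            d["controls"],
            d["observations"],
        )
        total, _ = sequence_loglik(res.predictions, d["observations"])
        assert total == pytest.approx(res.increments.sum(), abs=1e-9)
        assert total == pytest.approx(res.loglik, abs=1e-9)

    def test_iid_case_closed_form(self):
        # static state known exactly, identity observation: the predictive
        # density is N(y; x, R) at every step
        rng = np.random.default_rng(5)
        ys = rng.normal(0.7, 0.3, (40, 1))
        tr = LinearTransition(np.eye(1), np.zeros((1, 1)), np.zeros((1, 1)))
        obs = LinearObservation(np.eye(1), np.array([[0.09]]))
        prior = Belief(np.array([0.7]), np.zeros((1, 1)))
        res = forward_filter(tr, obs, prior, np.zeros((40, 1)), ys)
        expect = np.sum(
            -0.5 * ((ys[:, 0] - 0.7) ** 2 / 0.09 + np.log(2 * np.pi * 0.09))
        )
        # the tiny innovation floor shifts the density negligibly
        assert res.loglik == pytest.approx(expect, rel=1e-6)

    def test_modality_terms_sum_to_total(self, mini_model, mini_maze, rng):
        from navinfer import envsim

        tr = AgentTransition(Q=1e-6 * np.eye(4))
        prior = Belief(np.array([0.5, 0.5, 0.0, 0.0]), 1e-8 * np.eye(4))
        controls = np.tile([0.1, 0.05], (30, 1))
        obs = []
        x = prior.mean
        from navinfer.dynamics import step

        for t in range(30):
            x = step(x, controls[t])
            obs.append(envsim.observe(mini_maze, x, P=mini_model.P).vector)
        res = forward_filter(tr, mini_model, prior, controls, obs)
        total, per = sequence_loglik(res.predictions, obs, mini_model.modality_slices)
        assert sum(per.values()) == pytest.approx(total, abs=1e-10)


class TestBackwardSmooth:
    def _filter(self, d):
        return forward_filter(
            LinearTransition(d["A"], d["B"], d["Q"]),
            LinearObservation(d["H"], d["R"]),
            Belief(d["x0_mean"], d["x0_cov"]),
            d["controls"],
            d["observations"],
        )

    def test_final_smoothed_equals_final_filtered(self, toy_lds):
        res = self._filter(toy_lds)
        sm = backward_smooth(res)
        assert np.array_equal(sm[-1].mean, res.beliefs[-1].mean)
        assert np.array_equal(sm[-1].cov, res.beliefs[-1].cov)

    def test_matches_batch_joint_precision_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            A, B, H, Q, R = random_lds(rng)
            controls, ys = simulate_lds(rng, A, B, H, Q, R, 30)
            prior = Belief(np.zeros(3), np.eye(3))
            res = forward_filter(LinearTransition(A, B, Q), LinearObservation(H, R), prior, controls, ys)
            sm = backward_smooth(res)
            means, covs = oracles.batch_gaussian_smoother(A, B, H, Q, R, np.zeros(3), np.eye(3), controls, ys)
            assert np.allclose(np.array([s.mean for s in sm]), means, atol=1e-6)
            assert np.allclose(np.array([s.cov for s in sm]), covs, atol=1e-6)

    def test_smoothing_never_increases_uncertainty(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            A, B, H, Q, R = random_lds(rng)
            controls, ys = simulate_lds(rng, A, B, H, Q, R, 40)
            res = forward_filter(
                LinearTransition(A, B, Q), LinearObservation(H, R), Belief(np.zeros(3), np.eye(3)), controls, ys
            )
            sm = backward_smooth(res)
            for s, b in zip(sm, res.beliefs[1:]):
                assert np.trace(s.cov) <= np.trace(b.cov) + 1e-8


class TestRelativePrecisionForm:
    def test_posterior_mean_is_precision_weighted_average(self):
        # scalar linear case: the corrected mean must equal the
        # precision-weighted combination of the path-integral estimate and
        # the sensory estimate
        mu_pred, var_pred = 0.4, 0.2
        y, var_obs = 1.0, 0.3
        pred = infer.Prediction(
            mean=np.array([mu_pred]), cov=np.array([[var_pred]]), flow=np.eye(1)
        )
        belief, _ = correct_step(pred, np.array([y]), LinearObservation(np.eye(1), [[var_obs]]))
        expect = (mu_pred / var_pred + y / var_obs) / (1 / var_pred + 1 / var_obs)
        assert belief.mean[0] == pytest.approx(expect, abs=1e-9)


class TestLikelihoodSanity:
    def test_true_model_scores_higher_on_average(self):
        rng = np.random.default_rng(11)
        A, B, H, Q, R = random_lds(rng)
        A2 = 0.5 * A  # a distinctly different dynamical model
        wins = 0
        for _ in range(20):
            controls, ys = simulate_lds(rng, A, B, H, Q, R, 40)
            prior = Belief(np.zeros(3), np.eye(3))
            llA = forward_filter(LinearTransition(A, B, Q), LinearObservation(H, R), prior, controls, ys).loglik
            llB = forward_filter(LinearTransition(A2, B, Q), LinearObservation(H, R), prior, controls, ys).loglik
            wins += llA > llB
        assert wins >= 15


class TestInferInputs:
    def test_consistent_goals_keep_controls_at_zero(self, mini_model):
        # goals equal to the model's predictions at the resting prior state:
        # there is nothing for the controls to explain
        m = mini_model.with_overrides(include_speed=True)
        x0 = np.array([0.5, 0.5, 0.0, 0.0])
        goal = m.predict_vector(x0)
        tr = AgentTransition(Q=1e-10 * np.eye(4))
        prior = Belief(x0, 1e-10 * np.eye(4))
        cp = ControlEstimate(np.zeros(2), np.diag([1.0, 0.1]))
        _, _, ests = infer_inputs(m, tr, prior, np.tile(goal, (40, 1)), cp, 1e-6 * np.eye(2))
        u = np.array([e.mean for e in ests])
        assert np.max(np.abs(u)) < 1e-6

    def test_matches_batch_deconvolution_on_linear_system(self):
        rng = np.random.default_rng(21)
        A, B, H, Q, R = random_lds(rng)
        Q_u = 0.02 * np.eye(1)
        u0_cov = 0.5 * np.eye(1)
        goals = rng.normal(0, 1, (25, 2))
        prior = Belief(np.zeros(3), 0.1 * np.eye(3))
        cp = ControlEstimate(np.zeros(1), u0_cov)
        _, _, ests = infer_inputs(LinearObservation(H, R), LinearTransition(A, B, Q), prior, goals, cp, Q_u)
        u_hat = np.array([e.mean for e in ests])
        u_batch = oracles.batch_input_estimate(
            A, B, H, Q, R, Q_u, np.zeros(3), 0.1 * np.eye(3), np.zeros(1), u0_cov, goals
        )
        assert np.allclose(u_hat, u_batch, atol=1e-5)

    def test_control_recovery_improves_as_goal_noise_vanishes(self):
        rng = np.random.default_rng(3)
        A, B, H, Q, R = random_lds(rng)
        Qz = np.zeros_like(Q)
        true_u = 0.5 * np.sin(np.linspace(0, 3 * np.pi, 40))[:, None]
        x = np.zeros(3)
        clean = []
        for t in range(40):
            x = A @ x + B @ true_u[t]
            clean.append(H @ x)
        clean = np.array(clean)
        rmses = []
        for sd in (0.3, 0.03, 0.003):
            goals = clean + rng.normal(0, sd, clean.shape)
            prior = Belief(np.zeros(3), 1e-10 * np.eye(3))
            cp = ControlEstimate(np.zeros(1), np.eye(1))
            _, _, ests = infer_inputs(
                LinearObservation(H, sd**2 * np.eye(2) + 1e-9 * np.eye(2)),
                LinearTransition(A, B, Qz + 1e-10 * np.eye(3)),
                prior,
                goals,
                cp,
                0.1 * np.eye(1),
            )
            u_hat = np.array([e.mean for e in ests])
            # the control block at step t drives observation t+1
            rmses.append(np.sqrt(np.mean((u_hat[:-1] - true_u[1:]) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]
        assert rmses[2] < 0.05

    def test_simplified_mode_agrees_when_uncoupled(self):
        # with B = 0 the controls never correlate with the states, so the
        # decoupled backward recursion is exact
        rng = np.random.default_rng(4)
        A, _, H, Q, R = random_lds(rng)
        B = np.zeros((3, 1))
        goals = rng.normal(0, 1, (20, 2))
        prior = Belief(np.zeros(3), np.eye(3))
        cp = ControlEstimate(np.zeros(1), np.eye(1))
        args = (LinearObservation(H, R), LinearTransition(A, B, Q), prior, goals, cp, 0.05 * np.eye(1))
        _, _, full = infer_inputs(*args)
        _, _, simp = infer_inputs(*args, simplified=True)
        for a, b in zip(full, simp):
            assert np.allclose(a.mean, b.mean, atol=1e-8)
            assert np.allclose(a.cov, b.cov, atol=1e-8)
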