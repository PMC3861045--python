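"""Forward and backward Gaussian inference in the agent's state-space model.

Forward inference is an extended Kalman filter: the mean is propagated
through the exact nonlinear one-step map while covariances use the local
linearisation (flow matrices); the correction applies the Kalman gain to
the multisensory prediction error in Joseph-stabilised form. The sequence
log-likelihood accumulates the Gaussian predictive densities of the
innovations and decomposes additively over sensory modalities.

Backward inference is the RTS-form "gamma recursion" smoother, which
refines the filtered estimates retrospectively without re-visiting the
observations. Inference over unknown controls (planning) augments the
state with the control vector — the controls evolve as a random walk — and
reuses the same forward/backward machinery; the control marginals are read
out of the smoothed augmented beliefs.

The transition/observation interfaces are duck-typed so the same recursions
run on the navigation model, on the augmented planning model, and on plain
linear-Gaussian systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import dynamics as dyn
from .envsim import _check_psd

__all__ = [
    "Belief",
    "Prediction",
    "SmoothedBelief",
    "ControlEstimate",
    "AgentTransition",
    "LinearTransition",
    "LinearObservation",
    "AugmentedTransition",
    "AugmentedObservation",
    "predict_step",
    "correct_step",
    "forward_filter",
    "FilterResult",
    "sequence_loglik",
    "backward_smooth",
    "infer_inputs",
]

_COV_FLOOR = 1e-10
_LOG2PI = np.log(2.0 * np.pi)


def _symmetrise(S: np.ndarray) -> np.ndarray:
    return 0.5 * (S + S.T)


@dataclass
class Belief:
    """Gaussian belief over the hidden state."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = _symmetrise(np.asarray(self.cov, dtype=float))
        _check_psd(self.cov, "belief covariance")


@dataclass
class Prediction:
    """One-step prediction record, as needed by correction and smoothing."""

    mean: np.ndarray  # mu_{t|t-1}
    cov: np.ndarray  # Sigma_{t|t-1}
    flow: np.ndarray  # f_x at the linearisation point (for the smoother)
    predicted_obs: np.ndarray | None = None  # g(mu_{t|t-1})
    innov_cov: np.ndarray | None = None  # S_t = G Sigma G' + Phi
    obs_jac: np.ndarray | None = None  # G


@dataclass
class SmoothedBelief:
    mean: np.ndarray
    cov: np.ndarray
    gain: np.ndarray  # J_t


@dataclass
class ControlEstimate:
    """Gaussian over a 2-vector of controls (a, omega)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = _symmetrise(np.atleast_2d(np.asarray(self.cov, dtype=float)))
        _check_psd(self.cov, "control covariance")


# --------------------------------------------------------------------------
# transition / observation operators
# --------------------------------------------------------------------------
class AgentTransition:
    """Nonlinear agent dynamics wrapped as a filter transition model."""

    def __init__(self, dt: float = dyn.DEFAULT_DT, k: float = dyn.DEFAULT_K, Q: np.ndarray | None = None):
        self.dt = float(dt)
        self.k = float(k)
        self.Q = np.zeros((4, 4)) if Q is None else np.asarray(Q, dtype=float)
        _check_psd(self.Q, "state noise covariance Q")

    def mean(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        return dyn.step(x, u, dt=self.dt, k=self.k)

    def jacobians(self, x: np.ndarray, u: np.ndarray):
        fm = dyn.linearise(x, u, dt=self.dt, k=self.k, method="analytic")
        return fm.f_x, fm.f_u


class LinearTransition:
    """x_{t+1} = A x + B u + w, w ~ N(0, Q)."""

    def __init__(self, A, B, Q):
        self.A = np.atleast_2d(np.asarray(A, dtype=float))
        self.B = np.atleast_2d(np.asarray(B, dtype=float))
        self.Q = np.atleast_2d(np.asarray(Q, dtype=float))
        _check_psd(self.Q, "Q")

    def mean(self, x, u):
        return self.A @ x + self.B @ u

    def jacobians(self, x, u):
        return self.A, self.B


class LinearObservation:
    """y = H x + v, v ~ N(0, R)."""

    def __init__(self, H, R):
        self.H = np.atleast_2d(np.asarray(H, dtype=float))
        self.cov = np.atleast_2d(np.asarray(R, dtype=float))
        _check_psd(self.cov, "R")

    def predict_vector(self, x):
        return self.H @ x

    def jacobian(self, x):
        return self.H


class AugmentedTransition:
    """State (+) control augmentation: controls evolve as a random walk.

    The augmented state is ``z = (x, u)`` (dimension 4 + 2); the state block
    advances through the base transition driven by the control block, and
    the control block persists with innovation covariance ``Q_u``. Any
    externally supplied control is ignored.
    """

    def __init__(self, base, Q_u: np.ndarray):
        self.base = base
        self.Q_u = np.atleast_2d(np.asarray(Q_u, dtype=float))
        _check_psd(self.Q_u, "Q_u")
        self.nu = self.Q_u.shape[0]

    def mean(self, z, u_ext=None):
        x, u = z[: -self.nu], z[-self.nu :]
        return np.concatenate([self.base.mean(x, u), u])

    def jacobians(self, z, u_ext=None):
        x, u = z[: -self.nu], z[-self.nu :]
        Fx, Fu = self.base.jacobians(x, u)
        n = Fx.shape[0]
        F = np.zeros((n + self.nu, n + self.nu))
        F[:n, :n] = Fx
        F[:n, n:] = Fu
        F[n:, n:] = np.eye(self.nu)
        return F, np.zeros((n + self.nu, 0))

    @property
    def Q(self):
        return scipy.linalg.block_diag(self.base.Q, self.Q_u)


class AugmentedObservation:
    """Observation operator on the augmented state: reads the state block."""

    def __init__(self, obs_model, state_dim: int = 4):
        self.obs = obs_model
        self.state_dim = state_dim

    @property
    def cov(self):
        return self.obs.cov

    def predict_vector(self, z):
        return self.obs.predict_vector(z[: self.state_dim])

    def jacobian(self, z):
        G = self.obs.jacobian(z[: self.state_dim])
        return np.hstack([G, np.zeros((G.shape[0], z.size - self.state_dim))])


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------
def predict_step(belief: Belief, transition, control) -> Prediction:
    """Probabilistic path integration: propagate mean and covariance.

    The mean moves through the nonlinear one-step map; the covariance uses
    the flow matrix: ``Sigma^- = f_x Sigma f_x' + Q``.
    """
    u = np.asarray(getattr(control, "vector", control), dtype=float).ravel()
    F_x, _ = transition.jacobians(belief.mean, u)
    mu = transition.mean(belief.mean, u)
    cov = _symmetrise(F_x @ belief.cov @ F_x.T + transition.Q)
    return Prediction(mean=mu, cov=cov, flow=F_x)


def _chol_solve(S, B):
    c, low = scipy.linalg.cho_factor(S)
    return scipy.linalg.cho_solve((c, low), B)


def correct_step(pred: Prediction, observation, obs_model):
    """Kalman correction against one observation; returns (Belief, loglik).

    Fills the prediction record (predicted observation, innovation
    covariance, Jacobian) in place. The log-likelihood increment is the
    Gaussian predictive density of the innovation. A singular innovation
    covariance raises with a hint to raise the observation noise floor.
    """
    y = np.asarray(getattr(observation, "vector", observation), dtype=float).ravel()
    G = obs_model.jacobian(pred.mean)
    if G.shape[0] != y.size:
        raise ValueError(f"observation has {y.size} channels but the model predicts {G.shape[0]}")
    yhat = obs_model.predict_vector(pred.mean)
    S = _symmetrise(G @ pred.cov @ G.T + obs_model.cov) + _COV_FLOOR * np.eye(y.size)
    pred.predicted_obs = yhat
    pred.innov_cov = S
    pred.obs_jac = G
    try:
        c, low = scipy.linalg.cho_factor(S)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular innovation covariance; increase the observation noise floor"
        ) from exc
    K = scipy.linalg.cho_solve((c, low), G @ pred.cov).T  # Sigma G' S^-1
    e = y - yhat
    mean = pred.mean + K @ e
    I_KG = np.eye(pred.mean.size) - K @ G
    cov = _symmetrise(I_KG @ pred.cov @ I_KG.T + K @ obs_model.cov @ K.T)
    z = scipy.linalg.cho_solve((c, low), e)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    ll = -0.5 * (e @ z + logdet + y.size * _LOG2PI)
    return Belief(mean, cov), float(ll)


@dataclass
class FilterResult:
    """Forward-pass record: prior + filtered beliefs, predictions, loglik."""

    beliefs: list  # length T+1, element 0 is the prior
    predictions: list  # length T
    loglik: float
    increments: np.ndarray  # (T,)

    @property
    def filtered_means(self) -> np.ndarray:
        return np.array([b.mean for b in self.beliefs[1:]])

    @property
    def filtered_covs(self) -> np.ndarray:
        return np.array([b.cov for b in self.beliefs[1:]])


def forward_filter(
    transition,
    obs_model,
    prior: Belief,
    controls,
    observations,
    lesion: bool = False,
    predict_mean_noise: np.ndarray | None = None,
) -> FilterResult:
    """Alternate prediction and correction over a sequence.

    ``lesion=True`` removes the correction step entirely (the Kalman gain
    is forced to zero), leaving pure probabilistic path integration — the
    "lesioned hippocampus" variant. ``predict_mean_noise`` (T, n) is added
    to the predicted mean at each step and models an imperfect path
    integrator. Observations may be vectors or Observation objects; their
    count must match the controls.
    """
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    T = controls.shape[0]
    obs_list = list(observations)
    if len(obs_list) != T:
        raise ValueError(f"got {len(obs_list)} observations for {T} controls")
    if predict_mean_noise is not None:
        predict_mean_noise = np.asarray(predict_mean_noise, dtype=float)
        if predict_mean_noise.shape[0] != T:
            raise ValueError("predict_mean_noise must have one row per step")
    beliefs = [prior]
    predictions = []
    increments = np.zeros(T)
    total = 0.0
    belief = prior
    for t in range(T):
        pred = predict_step(belief, transition, controls[t])
        if predict_mean_noise is not None:
            pred.mean = pred.mean + predict_mean_noise[t]
        if lesion:
            belief = Belief(pred.mean, pred.cov)
            # still record the predictive quantities for likelihood use
            y = np.asarray(getattr(obs_list[t], "vector", obs_list[t]), dtype=float).ravel()
            G = obs_model.jacobian(pred.mean)
            pred.obs_jac = G
            pred.predicted_obs = obs_model.predict_vector(pred.mean)
            pred.innov_cov = _symmetrise(G @ pred.cov @ G.T + obs_model.cov) + _COV_FLOOR * np.eye(y.size)
            ll = _gaussian_loglik(y - pred.predicted_obs, pred.innov_cov)
        else:
            belief, ll = correct_step(pred, obs_list[t], obs_model)
        if not np.all(np.isfinite(belief.mean)):
            raise FloatingPointError(f"filter diverged at step {t}: non-finite mean")
        predictions.append(pred)
        beliefs.append(belief)
        increments[t] = ll
        total += ll
    return FilterResult(beliefs=beliefs, predictions=predictions, loglik=total, increments=increments)


def _gaussian_loglik(e: np.ndarray, S: np.ndarray) -> float:
    c, low = scipy.linalg.cho_factor(S)
    z = scipy.linalg.cho_solve((c, low), e)
    return float(-0.5 * (e @ z + 2.0 * np.sum(np.log(np.diag(c))) + e.size * _LOG2PI))


def sequence_loglik(predictions, observations, modality_slices: dict | None = None):
    """Total sequence log-likelihood and its per-modality decomposition.

    The total is the sum over time of the Gaussian predictive log-density
    of each observation. The decomposition conditions the channels
    sequentially in their stored order (olfaction, touch, vision, speed)
    through the Cholesky factor of the innovation covariance, so the
    modality terms sum to the total exactly and reduce to the marginal
    densities when cross-modality couplings vanish.

    Returns ``(total, per_modality)``; ``per_modality`` is ``{}`` when no
    slices are given.
    """
    obs_list = list(observations)
    if len(obs_list) != len(predictions):
        raise ValueError("predictions and observations must be aligned")
    total = 0.0
    per = {name: 0.0 for name in (modality_slices or {})}
    for pred, obs in zip(predictions, obs_list):
        y = np.asarray(getattr(obs, "vector", obs), dtype=float).ravel()
        e = y - pred.predicted_obs
        L = np.linalg.cholesky(pred.innov_cov)
        z = scipy.linalg.solve_triangular(L, e, lower=True)
        chan = -0.5 * (z**2 + 2.0 * np.log(np.diag(L)) + _LOG2PI)
        total += float(np.sum(chan))
        for name, sl in (modality_slices or {}).items():
            per[name] += float(np.sum(chan[sl]))
    return total, per


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------
def backward_smooth(result: FilterResult) -> list:
    """Gamma-recursion (RTS) smoother over a forward-filter record.

    Initialised with the last filtered belief; each step applies the
    smoother gain ``J_t = Sigma_{t|t} f_x' Sigma_{t+1|t}^{-1}`` to the
    backward prediction error. Returns smoothed beliefs for t = 1..T
    (aligned with ``result.beliefs[1:]``).
    """
    beliefs = result.beliefs
    preds = result.predictions
    T = len(preds)
    last = beliefs[T]
    smoothed = [SmoothedBelief(last.mean.copy(), last.cov.copy(), np.zeros_like(last.cov))]
    for t in range(T - 1, 0, -1):
        b = beliefs[t]  # filtered at t
        pred_next = preds[t]  # prediction of t+1 given t
        try:
            Jt = _chol_solve(pred_next.cov + _COV_FLOOR * np.eye(b.cov.shape[0]), pred_next.flow @ b.cov).T
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular predicted covariance in the smoother; regularise Q"
            ) from exc
        nxt = smoothed[0]
        mean = b.mean + Jt @ (nxt.mean - pred_next.mean)
        cov = _symmetrise(b.cov + Jt @ (nxt.cov - pred_next.cov) @ Jt.T)
        smoothed.insert(0, SmoothedBelief(mean, cov, Jt))
    return smoothed


# --------------------------------------------------------------------------
# inference over inputs (planning)
# --------------------------------------------------------------------------
def infer_inputs(
    obs_model,
    transition,
    prior_state: Belief,
    goals,
    control_prior: ControlEstimate,
    Q_u: np.ndarray,
    simplified: bool = False,
):
    """Estimate the control sequence that explains a goal observation sequence.

    Builds the augmented state-space model (state (+) control, the control
    evolving as a random walk with covariance ``Q_u`` from the given prior),
    runs the forward filter on the goals and smooths backward; the control
    marginals are extracted from the smoothed augmented beliefs. This is a
    model-based deconvolution of the desired sensory states.

    With ``simplified=True`` the backward pass additionally returns control
    marginals from the decoupled recursion that ignores state-control
    cross-covariances (a cross-check mode; exact only when those
    correlations vanish).

    Returns ``(result, smoothed, control_estimates)`` where ``result`` is the
    forward FilterResult on the augmented model and ``control_estimates`` is
    a list of ControlEstimate, one per step.
    """
    goals = np.atleast_2d(np.asarray(goals, dtype=float))
    if goals.shape[0] < 1:
        raise ValueError("goals must be non-empty")
    Q_u = np.atleast_2d(np.asarray(Q_u, dtype=float))
    _check_psd(Q_u, "Q_u")
    nu = Q_u.shape[0]
    aug_t = AugmentedTransition(transition, Q_u)
    aug_o = AugmentedObservation(obs_model, state_dim=prior_state.mean.size)
    prior = Belief(
        np.concatenate([prior_state.mean, control_prior.mean]),
        scipy.linalg.block_diag(prior_state.cov, control_prior.cov),
    )
    T = goals.shape[0]
    controls = np.zeros((T, 0))  # augmented model takes no external control
    result = forward_filter(aug_t, aug_o, prior, controls, goals)
    smoothed = backward_smooth(result)
    if simplified:
        ests = _simplified_control_smooth(result, nu)
    else:
        ests = [ControlEstimate(s.mean[-nu:], s.cov[-nu:, -nu:]) for s in smoothed]
    return result, smoothed, ests


def _simplified_control_smooth(result: FilterResult, nu: int):
    """Backward recursion on the control block alone (no cross-covariances)."""
    beliefs = result.beliefs
    preds = result.predictions
    T = len(preds)
    last = beliefs[T]
    out = [ControlEstimate(last.mean[-nu:], last.cov[-nu:, -nu:])]
    for t in range(T - 1, 0, -1):
        mu_f = beliefs[t].mean[-nu:]
        P_f = beliefs[t].cov[-nu:, -nu:]
        mu_p = preds[t].mean[-nu:]
        P_p = preds[t].cov[-nu:, -nu:]
        # control random walk: flow on the control block is the identity
        J = P_f @ np.linalg.inv(P_p + _COV_FLOOR * np.eye(nu))
        nxt = out[0]
        mean = mu_f + J @ (nxt.mean - mu_p)
        cov = _symmetrise(P_f + J @ (nxt.cov - P_p) @ J.T)
        out.insert(0, ControlEstimate(mean, cov))
    return out
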