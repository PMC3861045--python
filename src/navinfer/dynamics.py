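"""Agent dynamics: drift with friction, RK4 stepping and local linearisation.

The hidden state is ``x = (x, y, v, theta)``: allocentric position, speed
and heading (clockwise from +x, y-up, so ``ydot = -v sin(theta)``). Controls
``u = (a, omega)`` are rates — a speed drive (units/s^2) and a heading drive
(rad/s) — integrated over the time step, and speed is subject to linear
friction ``vdot = a - k v``.

The one-step map is integrated with a fixed-step 4th-order Runge-Kutta
scheme; its flow matrices (Jacobians of the discrete map with respect to
state and control) are available analytically, by central finite
differences, or by local least-squares regression over perturbed one-step
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envsim import _check_psd, sample_gaussian

__all__ = [
    "State",
    "Control",
    "FlowMatrices",
    "drift",
    "linearise",
    "step",
    "simulate_trajectory",
    "make_canonical_controls",
    "DEFAULT_DT",
    "DEFAULT_K",
    "DEFAULT_N_STEPS",
]

DEFAULT_DT = 0.01
DEFAULT_K = 1.0
DEFAULT_N_STEPS = 1000

STATE_DIM = 4
CONTROL_DIM = 2


@dataclass(frozen=True)
class State:
    x: float
    y: float
    v: float
    theta: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.x, self.y, self.v, self.theta], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "State":
        vec = np.asarray(vec, dtype=float).ravel()
        return cls(*vec[:4])

    @property
    def location(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class Control:
    a: float
    omega: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.a, self.omega], dtype=float)


@dataclass(frozen=True)
class FlowMatrices:
    """Discrete-time flow: ``x_{t+1} ~= f_x x_t + f_u u_t`` near a point."""

    f_x: np.ndarray  # (4, 4)
    f_u: np.ndarray  # (4, 2)


def _as_state(state) -> np.ndarray:
    x = np.asarray(getattr(state, "vector", state), dtype=float).ravel()
    if x.size != STATE_DIM or not np.all(np.isfinite(x)):
        raise ValueError(f"state must be a finite 4-vector, got {state!r}")
    return x


def _as_control(control) -> np.ndarray:
    u = np.asarray(getattr(control, "vector", control), dtype=float).ravel()
    if u.size != CONTROL_DIM or not np.all(np.isfinite(u)):
        raise ValueError(f"control must be a finite 2-vector, got {control!r}")
    return u


def drift(state, control, k: float = DEFAULT_K) -> np.ndarray:
    """Continuous-time state derivative ``(xdot, ydot, vdot, thetadot)``.

    ``(v cos(theta), -v sin(theta), a - k v, omega)`` with friction k >= 0.
    """
    if k < 0:
        raise ValueError("friction constant k must be >= 0")
    x = _as_state(state)
    u = _as_control(control)
    v, th = x[2], x[3]
    return np.array([v * np.cos(th), -v * np.sin(th), u[0] - k * v, u[1]])


def _drift_jacobians(x: np.ndarray, k: float):
    """Jacobians of the drift wrt state and control at ``x``."""
    v, th = x[2], x[3]
    A = np.zeros((4, 4))
    A[0, 2] = np.cos(th)
    A[0, 3] = -v * np.sin(th)
    A[1, 2] = -np.sin(th)
    A[1, 3] = -v * np.cos(th)
    A[2, 2] = -k
    B = np.zeros((4, 2))
    B[2, 0] = 1.0
    B[3, 1] = 1.0
    return A, B


def _rk4(x: np.ndarray, u: np.ndarray, dt: float, k: float) -> np.ndarray:
    f = lambda s: np.array(
        [s[2] * np.cos(s[3]), -s[2] * np.sin(s[3]), u[0] - k * s[2], u[1]]
    )
    k1 = f(x)
    k2 = f(x + 0.5 * dt * k1)
    k3 = f(x + 0.5 * dt * k2)
    k4 = f(x + dt * k3)
    return x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _rk4_jacobians(x: np.ndarray, u: np.ndarray, dt: float, k: float):
    """Exact Jacobians of the RK4 one-step map, by stage-wise chain rule."""
    I = np.eye(4)
    stages_x = []  # d k_i / d x
    stages_u = []  # d k_i / d u
    xs = x
    Dx = I
    Du = np.zeros((4, 2))
    coeffs = [0.0, 0.5, 0.5, 1.0]
    for i, c in enumerate(coeffs):
        if i > 0:
            xs = x + c * dt * kprev
            Dx = I + c * dt * stages_x[-1]
            Du = c * dt * stages_u[-1]
        A, B = _drift_jacobians(xs, k)
        stages_x.append(A @ Dx)
        stages_u.append(A @ Du + B)
        kprev = np.array(
            [xs[2] * np.cos(xs[3]), -xs[2] * np.sin(xs[3]), u[0] - k * xs[2], u[1]]
        )
    w = np.array([1.0, 2.0, 2.0, 1.0]) * dt / 6.0
    F_x = I + sum(wi * Ki for wi, Ki in zip(w, stages_x))
    F_u = sum(wi * Ki for wi, Ki in zip(w, stages_u))
    return F_x, F_u


def linearise(
    state,
    control,
    dt: float = DEFAULT_DT,
    k: float = DEFAULT_K,
    method: str = "analytic",
    rng: np.random.Generator | None = None,
    n_samples: int = 100,
    scale: float = 1e-3,
) -> FlowMatrices:
    """Flow matrices of the one-step map at a linearisation point.

    ``method='analytic'`` differentiates the RK4 map exactly;
    ``'finite-diff'`` uses central differences; ``'local-regression'`` fits
    ``(f_x, f_u)`` by least squares over ``n_samples`` perturbed one-step
    simulations (perturbation scale ``scale``), in the spirit of locally
    weighted regression approaches to model linearisation.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = _as_state(state)
    u = _as_control(control)
    if method == "analytic":
        F_x, F_u = _rk4_jacobians(x, u, dt, k)
        return FlowMatrices(F_x, F_u)
    if method == "finite-diff":
        h = 1e-6
        F_x = np.zeros((4, 4))
        F_u = np.zeros((4, 2))
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            F_x[:, j] = (_rk4(x + e, u, dt, k) - _rk4(x - e, u, dt, k)) / (2 * h)
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            F_u[:, j] = (_rk4(x, u + e, dt, k) - _rk4(x, u - e, dt, k)) / (2 * h)
        return FlowMatrices(F_x, F_u)
    if method == "local-regression":
        if rng is None:
            rng = np.random.default_rng(0)
        if n_samples < STATE_DIM + CONTROL_DIM + 1:
            raise ValueError(
                f"local regression needs at least {STATE_DIM + CONTROL_DIM + 1} samples"
            )
        dX = rng.normal(0.0, scale, size=(n_samples, 4))
        dU = rng.normal(0.0, scale, size=(n_samples, 2))
        base = _rk4(x, u, dt, k)
        Y = np.array([_rk4(x + dX[i], u + dU[i], dt, k) - base for i in range(n_samples)])
        D = np.hstack([dX, dU])  # (n, 6)
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        if np.linalg.matrix_rank(D) < 6:
            raise np.linalg.LinAlgError("singular regression design: too few samples")
        return FlowMatrices(coef.T[:, :4], coef.T[:, 4:])
    raise ValueError(f"unknown linearisation method {method!r}")


def step(
    state,
    control,
    dt: float = DEFAULT_DT,
    k: float = DEFAULT_K,
    Q: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One discrete step: RK4 mean propagation plus Gaussian state noise."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = _as_state(state)
    u = _as_control(control)
    xn = _rk4(x, u, dt, k)
    if Q is not None:
        _check_psd(np.asarray(Q, float), "state noise covariance Q")
        if rng is None:
            raise ValueError("rng is required when Q is given")
        xn = xn + sample_gaussian(np.asarray(Q, float), rng)
    return xn


def simulate_trajectory(
    x0,
    controls,
    dt: float = DEFAULT_DT,
    k: float = DEFAULT_K,
    Q: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Chain ``step`` over a control sequence; returns an (n+1, 4) array.

    Row 0 is the initial state; row t is the state after applying control
    ``controls[t-1]``.
    """
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    if controls.shape[0] == 0:
        raise ValueError("controls must be non-empty")
    x = _as_state(x0)
    out = np.empty((controls.shape[0] + 1, 4))
    out[0] = x
    for t, u in enumerate(controls):
        x = step(x, u, dt=dt, k=k, Q=Q, rng=rng)
        out[t + 1] = x
    return out


def make_canonical_controls(
    kind: str,
    n: int = DEFAULT_N_STEPS,
    dt: float = DEFAULT_DT,
    accel: float = 0.1,
    turn: float = 0.8 * np.pi * 0.3,
):
    """Canonical curved-trajectory controls and the matching initial heading.

    The speed drive is a sustained accelerate-then-coast profile (``accel``
    over the first half of the steps, then zero, so friction brings the
    agent to rest) and the heading drive is a smooth raised-cosine pulse
    over steps 10-40% integrating to a total turn of ``turn`` radians.

    ``kind`` selects one of the four compass trajectories: NE and NW start
    heading north (theta0 = -pi/2) and turn clockwise/anticlockwise
    respectively; SE and SW start heading south (theta0 = +pi/2). NW equals
    NE with the heading drive sign-flipped, and SE/SW are the mirror images
    obtained by flipping the initial heading.

    Returns ``(controls, theta0)`` with controls shaped (n, 2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kind = kind.upper()
    signs = {"NE": (-np.pi / 2, +1), "NW": (-np.pi / 2, -1), "SW": (np.pi / 2, +1), "SE": (np.pi / 2, -1)}
    if kind not in signs:
        raise ValueError(f"unknown trajectory kind {kind!r}; expected one of {sorted(signs)}")
    theta0, sgn = signs[kind]
    a = np.zeros(n)
    a[: max(1, n // 2)] = accel
    omega = np.zeros(n)
    lo, hi = int(round(0.1 * n)), int(round(0.4 * n))
    w = max(1, hi - lo)
    env = 1.0 - np.cos(2 * np.pi * (np.arange(w) + 0.5) / w)  # raised cosine
    omega[lo : lo + w] = sgn * turn * env / (env.sum() * dt)
    return np.column_stack([a, omega]), theta0
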