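"""Independent reference implementations used as test oracles.

Everything here is written directly from textbook definitions (explicit
matrix inversions, batch joint-Gaussian algebra, brute-force geometry) and
deliberately shares no code with the package's recursive implementations.
"""

import numpy as np


def kalman_filter(A, B, H, Q, R, x0_mean, x0_cov, controls, observations):
    """Plain textbook Kalman filter with explicit inverses.

    Returns (filtered_means, filtered_covs, predicted_means, predicted_covs,
    total_loglik).
    """
    x, P = np.array(x0_mean, float), np.array(x0_cov, float)
    ms, Ps, pm, pP = [], [], [], []
    ll = 0.0
    d = H.shape[0]
    for u, y in zip(controls, observations):
        x = A @ x + B @ u
        P = A @ P @ A.T + Q
        pm.append(x.copy())
        pP.append(P.copy())
        S = H @ P @ H.T + R + 1e-10 * np.eye(d)
        e = y - H @ x
        K = P @ H.T @ np.linalg.inv(S)
        ll += -0.5 * (e @ np.linalg.inv(S) @ e + np.log(np.linalg.det(S)) + d * np.log(2 * np.pi))
        x = x + K @ e
        P = (np.eye(P.shape[0]) - K @ H) @ P
        ms.append(x.copy())
        Ps.append(P.copy())
    return np.array(ms), np.array(Ps), np.array(pm), np.array(pP), ll


def batch_gaussian_smoother(A, B, H, Q, R, x0_mean, x0_cov, controls, observations):
    """Batch posterior over the full state sequence by joint-precision algebra.

    Builds the joint Gaussian over (x_1, ..., x_T) implied by the linear
    dynamical system, conditions on all observations at once by inverting
    the full block precision matrix, and returns the marginal means and
    covariances. Equivalent to any two-filter/beta-recursion smoother.
    """
    T = len(observations)
    n = A.shape[0]
    N = T * n
    Qi = np.linalg.inv(Q)
    Ri = np.linalg.inv(R)
    P0i = np.linalg.inv(x0_cov)
    Lam = np.zeros((N, N))
    eta = np.zeros(N)

    def blk(t):
        return slice(t * n, (t + 1) * n)

    # transition x_1 | x_0 with Gaussian prior on x_0 marginalised:
    # x_1 ~ N(A x0_mean + B u_0, A P0 A' + Q)
    P1 = A @ x0_cov @ A.T + Q
    P1i = np.linalg.inv(P1)
    Lam[blk(0), blk(0)] += P1i
    eta[blk(0)] += P1i @ (A @ np.array(x0_mean, float) + B @ controls[0])
    for t in range(1, T):
        # x_{t+1} = A x_t + B u_t + w
        Lam[blk(t - 1), blk(t - 1)] += A.T @ Qi @ A
        Lam[blk(t - 1), blk(t)] += -A.T @ Qi
        Lam[blk(t), blk(t - 1)] += -Qi @ A
        Lam[blk(t), blk(t)] += Qi
        eta[blk(t)] += Qi @ (B @ controls[t])
        eta[blk(t - 1)] += -A.T @ Qi @ (B @ controls[t])
    for t in range(T):
        Lam[blk(t), blk(t)] += H.T @ Ri @ H
        eta[blk(t)] += H.T @ Ri @ np.asarray(observations[t], float)
    Sigma = np.linalg.inv(Lam)
    mean = Sigma @ eta
    means = mean.reshape(T, n)
    covs = np.array([Sigma[blk(t), blk(t)] for t in range(T)])
    return means, covs


def batch_input_estimate(A, B, H, Q, R, Q_u, x0_mean, x0_cov, u0_mean, u0_cov, goals):
    """Batch MAP controls for the augmented random-walk-control model.

    Treats z_t = (x_t, u_t) with u_{t+1} = u_t + eps, eps ~ N(0, Q_u), and
    computes the exact posterior marginals of u_t given the goal sequence
    by the batch joint-precision construction. Returns (T, nu) means.
    """
    n, nu = A.shape[0], B.shape[1]
    Aa = np.block([[A, B], [np.zeros((nu, n)), np.eye(nu)]])
    Ba = np.zeros((n + nu, 1))
    Ha = np.hstack([H, np.zeros((H.shape[0], nu))])
    Qa = np.block([[Q, np.zeros((n, nu))], [np.zeros((nu, n)), Q_u]])
    z0_mean = np.concatenate([x0_mean, u0_mean])
    z0_cov = np.block([[x0_cov, np.zeros((n, nu))], [np.zeros((nu, n)), u0_cov]])
    controls = np.zeros((len(goals), 1))
    means, _ = batch_gaussian_smoother(Aa, Ba, Ha, Qa, R, z0_mean, z0_cov, controls, goals)
    return means[:, n:]


def ray_hit(origin, direction, p1, p2):
    """Brute-force ray/segment intersection via the 2x2 linear system."""
    M = np.column_stack([direction, np.asarray(p1, float) - np.asarray(p2, float)])
    if abs(np.linalg.det(M)) < 1e-14:
        return None
    t, s = np.linalg.solve(M, np.asarray(p1, float) - np.asarray(origin, float))
    if t > 1e-9 and -1e-9 <= s <= 1 + 1e-9:
        return t
    return None


def nearest_wall_hit(maze, origin, angle):
    """Independent ray cast: loop over walls, keep the nearest hit."""
    direction = np.array([np.cos(angle), -np.sin(angle)])
    best = (np.inf, None)
    for w in maze.walls:
        t = ray_hit(origin, direction, w.p1, w.p2)
        if t is not None and t < best[0]:
            best = (t, w.colour)
    return best
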