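"""The agent's learned observation model ``g(x; M_i)``.

Olfactory and somatosensory (touch) channels are linear read-outs of a grid
of idealised place cells (isotropic Gaussian bumps; 10-by-10 by default).
Each retinal pixel is a linear read-out of the conjunctive product of the
place basis with a bank of head-direction cells (von-Mises-shaped tuning;
32 cells by default, giving a 3200-dimensional conjunctive basis), with the
head-direction bank evaluated at the pixel's own retinal offset. Weights
are learned for each environment by (ridge) least squares on exemplars with
known states; an optional speed channel observes ``v`` directly and is used
only for motor planning.

The per-modality observation noise variances order the modalities'
influence during inference: olfaction and touch are trusted most, vision
least.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.linalg

from . import envsim
from .envsim import DEFAULT_P, Maze, Observation, retinal_angles

__all__ = [
    "PlaceBasis",
    "HDBasis",
    "SensoryModel",
    "place_activations",
    "hd_activations",
    "fit",
    "train_on_environment",
    "DEFAULT_NOISE",
]

#: default per-modality observation noise (variances)
DEFAULT_NOISE = {"sigma_o2": 0.01, "sigma_d2": 0.01, "sigma_v2": 0.1, "sigma_speed2": 0.01}


@dataclass(frozen=True)
class PlaceBasis:
    """Grid of isotropic Gaussian place fields."""

    centres: np.ndarray  # (B, 2)
    sigma: float

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centres, dtype=float))
        object.__setattr__(self, "centres", c)
        if self.sigma <= 0:
            raise ValueError("place-field width sigma must be > 0")

    @property
    def B(self) -> int:
        return self.centres.shape[0]

    @classmethod
    def grid(cls, bounds=(0.0, 1.0, 0.0, 1.0), nx: int = 10, ny: int = 10, sigma: float | None = None) -> "PlaceBasis":
        """Cell-centred nx-by-ny grid over the maze bounds.

        The default width equals the grid spacing, giving smoothly
        overlapping fields.
        """
        xmin, xmax, ymin, ymax = bounds
        xs = xmin + (np.arange(nx) + 0.5) * (xmax - xmin) / nx
        ys = ymin + (np.arange(ny) + 0.5) * (ymax - ymin) / ny
        cx, cy = np.meshgrid(xs, ys, indexing="ij")
        centres = np.column_stack([cx.ravel(), cy.ravel()])
        if sigma is None:
            sigma = (xmax - xmin) / nx
        return cls(centres=centres, sigma=float(sigma))


@dataclass(frozen=True)
class HDBasis:
    """Bank of head-direction cells with von-Mises-shaped tuning.

    Cell j responds ``exp(beta * (cos(angle - psi_j) - 1))``: maximal (1) at
    its preferred angle ``psi_j`` and 2-pi-periodic; ``beta`` sets the
    sharpness (beta = 10 gives roughly +-25 degrees at half height).
    """

    preferred_angles: np.ndarray  # (J,)
    beta: float = 10.0

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.preferred_angles, dtype=float))
        object.__setattr__(self, "preferred_angles", a)
        if self.beta <= 0:
            raise ValueError("head-direction precision beta must be > 0")
        wrapped = np.sort(np.mod(a, 2 * np.pi))
        if a.size > 1 and np.any(np.diff(wrapped) < 1e-12):
            raise ValueError("preferred angles must be distinct modulo 2*pi")

    @property
    def J(self) -> int:
        return self.preferred_angles.size

    @classmethod
    def uniform(cls, J: int = 32, beta: float = 10.0) -> "HDBasis":
        return cls(preferred_angles=np.arange(J) * 2 * np.pi / J, beta=beta)


def place_activations(basis: PlaceBasis, location) -> np.ndarray:
    """Activation of each place cell at one location (values in (0, 1])."""
    loc = np.asarray(location, dtype=float).reshape(2)
    if not np.all(np.isfinite(loc)):
        raise ValueError("location must be finite")
    d2 = np.sum((basis.centres - loc) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * basis.sigma**2))


def _place_batch(basis: PlaceBasis, locations) -> np.ndarray:
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    d2 = np.sum((locs[:, None, :] - basis.centres[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * basis.sigma**2))


def hd_activations(basis: HDBasis, angle) -> np.ndarray:
    """Activation of each head-direction cell at one or more angles."""
    a = np.asarray(angle, dtype=float)
    return np.exp(basis.beta * (np.cos(a[..., None] - basis.preferred_angles) - 1.0))


@dataclass
class SensoryModel:
    """Learned multisensory observation model for one environment.

    Channel order of the observation vector: olfaction, touch, the P
    retinal pixels, then (when ``include_speed``) the speed channel.
    ``W_v`` is stored as (P, B, J); ``W_v_flat`` exposes the (B*J, P) view.
    """

    place: PlaceBasis
    hd: HDBasis
    w_o: np.ndarray  # (B,)
    w_s: np.ndarray  # (B,)
    W_v: np.ndarray  # (P, B, J)
    sigma_o2: float = DEFAULT_NOISE["sigma_o2"]
    sigma_d2: float = DEFAULT_NOISE["sigma_d2"]
    Sigma_v: np.ndarray | None = None  # (P, P); default sigma_v2 * I
    sigma_speed2: float = DEFAULT_NOISE["sigma_speed2"]
    include_speed: bool = False

    def __post_init__(self):
        self.w_o = np.asarray(self.w_o, dtype=float).ravel()
        self.w_s = np.asarray(self.w_s, dtype=float).ravel()
        self.W_v = np.asarray(self.W_v, dtype=float)
        B, J = self.place.B, self.hd.J
        if self.w_o.size != B or self.w_s.size != B:
            raise ValueError("olfactory/somatosensory weight shapes inconsistent with basis")
        if self.W_v.ndim != 3 or self.W_v.shape[1:] != (B, J):
            raise ValueError(f"W_v must be (P, {B}, {J}), got {self.W_v.shape}")
        if self.Sigma_v is None:
            self.Sigma_v = DEFAULT_NOISE["sigma_v2"] * np.eye(self.P)
        self.Sigma_v = np.asarray(self.Sigma_v, dtype=float)
        envsim._check_psd(self.Sigma_v, "Sigma_v")
        self._alphas = retinal_angles(self.P)

    @property
    def P(self) -> int:
        return self.W_v.shape[0]

    @property
    def conjunctive_dim(self) -> int:
        """Size of the conjunctive place-by-head-direction basis (B * J)."""
        return self.place.B * self.hd.J

    @property
    def W_v_flat(self) -> np.ndarray:
        return self.W_v.reshape(self.P, -1).T

    @property
    def n_channels(self) -> int:
        return 2 + self.P + (1 if self.include_speed else 0)

    @property
    def modality_slices(self) -> dict:
        s = {"olfaction": slice(0, 1), "touch": slice(1, 2), "vision": slice(2, 2 + self.P)}
        if self.include_speed:
            s["speed"] = slice(2 + self.P, 3 + self.P)
        return s

    def noise_cov(self) -> np.ndarray:
        """Block-diagonal observation covariance Phi over the modalities."""
        blocks = [np.array([[self.sigma_o2]]), np.array([[self.sigma_d2]]), self.Sigma_v]
        if self.include_speed:
            blocks.append(np.array([[self.sigma_speed2]]))
        return scipy.linalg.block_diag(*blocks)

    # alias used by the inference code (observation-operator interface)
    @property
    def cov(self) -> np.ndarray:
        return self.noise_cov()

    def with_overrides(self, **kwargs) -> "SensoryModel":
        """Copy with per-task noise/flag overrides (e.g. ``sigma_d2=1e6``)."""
        return replace(self, **kwargs)

    # --- prediction and Jacobian -----------------------------------------
    def predict_vector(self, state) -> np.ndarray:
        x = np.asarray(getattr(state, "vector", state), dtype=float).ravel()
        phi = place_activations(self.place, x[:2])
        H = hd_activations(self.hd, x[3] + self._alphas)  # (P, J)
        out = np.empty(self.n_channels)
        out[0] = self.w_o @ phi
        out[1] = self.w_s @ phi
        out[2 : 2 + self.P] = np.einsum("pbj,b,pj->p", self.W_v, phi, H)
        if self.include_speed:
            out[2 + self.P] = x[2]
        return out

    def predict(self, state) -> Observation:
        return Observation.from_vector(self.predict_vector(state), self.P, self.include_speed)

    def jacobian(self, state) -> np.ndarray:
        """(n_channels, 4) Jacobian of the prediction wrt (x, y, v, theta)."""
        x = np.asarray(getattr(state, "vector", state), dtype=float).ravel()
        loc, theta = x[:2], x[3]
        phi = place_activations(self.place, loc)
        # d phi_b / d (x, y) = -phi_b * (loc - c_b) / sigma^2
        Dphi = -phi[:, None] * (loc[None, :] - self.place.centres) / self.place.sigma**2  # (B,2)
        ang = theta + self._alphas
        H = hd_activations(self.hd, ang)  # (P, J)
        dH = -self.hd.beta * np.sin(ang[:, None] - self.hd.preferred_angles[None, :]) * H
        G = np.zeros((self.n_channels, 4))
        G[0, :2] = self.w_o @ Dphi
        G[1, :2] = self.w_s @ Dphi
        G[2 : 2 + self.P, :2] = np.einsum("pbj,bq,pj->pq", self.W_v, Dphi, H)
        G[2 : 2 + self.P, 3] = np.einsum("pbj,b,pj->p", self.W_v, phi, dH)
        if self.include_speed:
            G[2 + self.P, 2] = 1.0
        return G

    # --- serialisation ----------------------------------------------------
    def save(self, directory) -> None:
        """Write the model as a JSON manifest plus CSV weight matrices."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "sigma_o2": self.sigma_o2,
            "sigma_d2": self.sigma_d2,
            "sigma_speed2": self.sigma_speed2,
            "include_speed": self.include_speed,
            "P": self.P,
            "place": {"sigma": self.place.sigma},
            "hd": {"beta": self.hd.beta},
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savetxt(d / "place_centres.csv", self.place.centres, delimiter=",")
        np.savetxt(d / "hd_angles.csv", self.hd.preferred_angles, delimiter=",")
        np.savetxt(d / "w_o.csv", self.w_o, delimiter=",")
        np.savetxt(d / "w_s.csv", self.w_s, delimiter=",")
        np.savetxt(d / "W_v.csv", self.W_v.reshape(self.P, -1), delimiter=",")
        np.savetxt(d / "Sigma_v.csv", self.Sigma_v, delimiter=",")

    @classmethod
    def load(cls, directory) -> "SensoryModel":
        d = Path(directory)
        m = json.loads((d / "manifest.json").read_text())
        place = PlaceBasis(np.loadtxt(d / "place_centres.csv", delimiter=",", ndmin=2), m["place"]["sigma"])
        hd = HDBasis(np.loadtxt(d / "hd_angles.csv", delimiter=",", ndmin=1), m["hd"]["beta"])
        W_v = np.loadtxt(d / "W_v.csv", delimiter=",", ndmin=2).reshape(m["P"], place.B, hd.J)
        return cls(
            place=place,
            hd=hd,
            w_o=np.loadtxt(d / "w_o.csv", delimiter=","),
            w_s=np.loadtxt(d / "w_s.csv", delimiter=","),
            W_v=W_v,
            sigma_o2=m["sigma_o2"],
            sigma_d2=m["sigma_d2"],
            Sigma_v=np.loadtxt(d / "Sigma_v.csv", delimiter=",", ndmin=2),
            sigma_speed2=m["sigma_speed2"],
            include_speed=m["include_speed"],
        )


def _ridge_solve(X: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """Solve min ||X w - Y||^2 + ridge ||w||^2 column-wise via Cholesky."""
    A = X.T @ X + ridge * np.eye(X.shape[1])
    b = X.T @ Y
    if ridge == 0.0:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient regression design; use ridge > 0 to regularise"
            )
        return np.linalg.solve(A, b)
    c, low = scipy.linalg.cho_factor(A)
    return scipy.linalg.cho_solve((c, low), b)


def fit(
    place: PlaceBasis,
    hd: HDBasis,
    states,
    observations,
    ridge: float = 1e-6,
    noise: dict | None = None,
    include_speed: bool = False,
    estimate_noise: bool = False,
) -> SensoryModel:
    """Fit all weights by (ridge) least squares on exemplars with known states.

    ``states`` is (N, 4) (or a sequence of State) and ``observations`` is
    (N, 2+P) (or a sequence of Observation; any speed channel is ignored —
    speed is observed directly and carries no weights). With
    ``estimate_noise`` the per-modality noise variances are replaced by the
    training residual variances.
    """
    X = np.array([np.asarray(getattr(s, "vector", s), dtype=float).ravel()[:4] for s in states])
    Yv = np.array([np.asarray(getattr(o, "vector", o), dtype=float).ravel() for o in observations])
    if X.shape[0] != Yv.shape[0] or X.shape[0] < 1:
        raise ValueError("states and observations must be aligned and non-empty")
    P = Yv.shape[1] - 2
    if P < 1:
        raise ValueError("observations must have at least one retinal channel")
    Phi_mat = _place_batch(place, X[:, :2])  # (N, B)
    w_os = _ridge_solve(Phi_mat, Yv[:, :2], ridge)  # (B, 2)
    alphas = retinal_angles(P)
    W_v = np.empty((P, place.B, hd.J))
    for p in range(P):
        Hp = hd_activations(hd, X[:, 3] + alphas[p])  # (N, J)
        Xp = Phi_mat[:, :, None] * Hp[:, None, :]  # (N, B, J)
        Xp = Xp.reshape(X.shape[0], -1)
        W_v[p] = _ridge_solve(Xp, Yv[:, 2 + p], ridge).reshape(place.B, hd.J)
    kwargs = dict(DEFAULT_NOISE)
    if noise:
        kwargs.update(noise)
    model = SensoryModel(
        place=place,
        hd=hd,
        w_o=w_os[:, 0],
        w_s=w_os[:, 1],
        W_v=W_v,
        sigma_o2=kwargs["sigma_o2"],
        sigma_d2=kwargs["sigma_d2"],
        Sigma_v=kwargs["sigma_v2"] * np.eye(P),
        sigma_speed2=kwargs["sigma_speed2"],
        include_speed=include_speed,
    )
    if estimate_noise:
        pred = np.array([model.predict_vector(x)[: 2 + P] for x in X])
        resid = Yv[:, : 2 + P] - pred
        model.sigma_o2 = float(np.var(resid[:, 0]))
        model.sigma_d2 = float(np.var(resid[:, 1]))
        model.Sigma_v = np.diag(np.var(resid[:, 2:], axis=0))
    return model


def training_grid(maze: Maze, n_loc_side: int = 15, n_headings: int = 47):
    """Default training design: cell-centred location grid x uniform headings.

    15x15 locations give 225 olfactory/touch exemplars; paired with 47
    headings they give 10,575 visual exemplars.
    """
    xmin, xmax, ymin, ymax = maze.bounds
    xs = xmin + (np.arange(n_loc_side) + 0.5) * (xmax - xmin) / n_loc_side
    ys = ymin + (np.arange(n_loc_side) + 0.5) * (ymax - ymin) / n_loc_side
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    locations = np.column_stack([gx.ravel(), gy.ravel()])
    headings = np.arange(n_headings) * 2 * np.pi / n_headings
    return locations, headings


def train_on_environment(
    maze: Maze,
    place: PlaceBasis | None = None,
    hd: HDBasis | None = None,
    P: int = DEFAULT_P,
    n_loc_side: int = 15,
    n_headings: int = 47,
    ridge: float = 1e-6,
    noise: dict | None = None,
    include_speed: bool = False,
) -> SensoryModel:
    """Learn a model of one environment on the standard exemplar grid.

    Exploits the product structure of the design (every location paired
    with every heading) so the conjunctive normal matrix factorises as a
    Kronecker product ``C_phi (x) C_h``, solved per pixel in the joint
    eigenbasis of the two factors. Exemplars are noiseless environmental
    observations (olfaction, touch and ray-cast retina).
    """
    if place is None:
        place = PlaceBasis.grid(maze.bounds)
    if hd is None:
        hd = HDBasis.uniform()
    locations, headings = training_grid(maze, n_loc_side, n_headings)
    n_loc, n_head = locations.shape[0], headings.size

    o_t = np.array([envsim.olfactory_signal(maze.source, l) for l in locations])
    d_t = np.array([envsim.min_wall_distance(maze, l) for l in locations])
    Phi_mat = _place_batch(place, locations)  # (n_loc, B)
    w_os = _ridge_solve(Phi_mat, np.column_stack([o_t, d_t]), ridge)

    # visual targets: (n_loc, n_head, P)
    locs_rep = np.repeat(locations, n_head, axis=0)
    heads_rep = np.tile(headings, n_loc)
    Y = envsim.render_retina_batch(maze, locs_rep, heads_rep, P).reshape(n_loc, n_head, P)

    C_phi = Phi_mat.T @ Phi_mat  # (B, B)
    lam_phi, U = np.linalg.eigh(C_phi)
    alphas = retinal_angles(P)
    W_v = np.empty((P, place.B, hd.J))
    for p in range(P):
        Hp = hd_activations(hd, headings + alphas[p])  # (n_head, J)
        C_h = Hp.T @ Hp
        mu_h, V = np.linalg.eigh(C_h)
        M = Phi_mat.T @ Y[:, :, p] @ Hp  # (B, J)
        denom = lam_phi[:, None] * mu_h[None, :] + ridge
        W_v[p] = U @ ((U.T @ M @ V) / denom) @ V.T

    kwargs = dict(DEFAULT_NOISE)
    if noise:
        kwargs.update(noise)
    return SensoryModel(
        place=place,
        hd=hd,
        w_o=w_os[:, 0],
        w_s=w_os[:, 1],
        W_v=W_v,
        sigma_o2=kwargs["sigma_o2"],
        sigma_d2=kwargs["sigma_d2"],
        Sigma_v=kwargs["sigma_v2"] * np.eye(P),
        sigma_speed2=kwargs["sigma_speed2"],
        include_speed=include_speed,
    )
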