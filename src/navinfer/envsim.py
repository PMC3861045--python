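"""Ground-truth 2D maze environment.

The environment is a closed rectangular arena with coloured wall segments
(four boundary walls plus optional inner walls), a single isotropically
diffusing olfactory source, a whisker-like touch sense returning the minimum
Euclidean distance to any wall, and a one-dimensional retina that samples
wall colour by ray casting over a 90 degree field of view centred on the
agent's heading.

Coordinate conventions (shared across the package):

* allocentric ``(x, y)`` with the y axis pointing up ("north" = max-y),
* headings in radians measured *clockwise* from the positive x axis, so a
  heading of ``-pi/2`` points north and ``+pi/2`` points south; the unit
  direction vector of heading ``a`` is ``(cos a, -sin a)``.

Walls carry a scalar colour in ``(0, 1)``; the defaults are 0.14 (north
border), 0.29 (east border), 0.43 (south border), 0.57 (west border), 0.71
(inner west wall) and 0.86 (inner east wall).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "WallSegment",
    "OdourSource",
    "Maze",
    "Observation",
    "olfactory_signal",
    "cast_ray",
    "cast_rays",
    "min_wall_distance",
    "render_retina",
    "retinal_angles",
    "observe",
    "swap_border_colours",
    "DEFAULT_P",
]

#: number of retinal pixels
DEFAULT_P = 20

#: half field of view of the retina (radians); pixels span [-FOV, +FOV]
RETINA_HALF_FOV = np.pi / 4.0

_EPS = 1e-12


def _vec2(p, name: str) -> np.ndarray:
    v = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be a finite 2-vector, got {p!r}")
    return v


@dataclass(frozen=True)
class WallSegment:
    """A straight wall from ``p1`` to ``p2`` with a scalar colour."""

    p1: np.ndarray
    p2: np.ndarray
    colour: float

    def __post_init__(self):
        object.__setattr__(self, "p1", _vec2(self.p1, "p1"))
        object.__setattr__(self, "p2", _vec2(self.p2, "p2"))
        if not np.isfinite(self.colour):
            raise ValueError("wall colour must be finite")
        if np.allclose(self.p1, self.p2):
            raise ValueError("degenerate wall: p1 == p2")


@dataclass(frozen=True)
class OdourSource:
    """Isotropic olfactory source: signal ``s * exp(-distance / lam)``."""

    location: np.ndarray
    scale: float = 1.0
    diffusion: float = 0.3

    def __post_init__(self):
        object.__setattr__(self, "location", _vec2(self.location, "source location"))
        if self.scale <= 0:
            raise ValueError("source scale must be > 0")
        if self.diffusion <= 0:
            raise ValueError("source diffusion length must be > 0")


# default wall colours, matching the simulated arena
BORDER_COLOURS = {"north": 0.14, "east": 0.29, "south": 0.43, "west": 0.57}
INNER_COLOURS = {"west_wall": 0.71, "east_wall": 0.86}


@dataclass
class Maze:
    """A closed rectangular maze: boundary walls, inner walls, odour source."""

    walls: list
    source: OdourSource
    bounds: tuple  # (xmin, xmax, ymin, ymax)

    def __post_init__(self):
        xmin, xmax, ymin, ymax = self.bounds
        if not (xmin < xmax and ymin < ymax):
            raise ValueError("invalid bounds")
        for w in self.walls:
            for p in (w.p1, w.p2):
                if not (xmin - _EPS <= p[0] <= xmax + _EPS and ymin - _EPS <= p[1] <= ymax + _EPS):
                    raise ValueError("wall endpoint outside bounds")
        self._segs = np.array([[w.p1, w.p2] for w in self.walls])  # (W, 2, 2)
        self._colours = np.array([w.colour for w in self.walls])

    @classmethod
    def default(cls) -> "Maze":
        """Unit-square arena with two inner walls forming offset corridors.

        The inner west wall runs from (0.35, 0.0) to (0.35, 0.6) and the
        inner east wall from (0.65, 0.4) to (0.65, 1.0), so a route between
        the left and right halves of the maze requires chained turns. The
        olfactory source sits in the south-west corner.
        """
        walls = [
            WallSegment((0.0, 1.0), (1.0, 1.0), BORDER_COLOURS["north"]),
            WallSegment((1.0, 0.0), (1.0, 1.0), BORDER_COLOURS["east"]),
            WallSegment((0.0, 0.0), (1.0, 0.0), BORDER_COLOURS["south"]),
            WallSegment((0.0, 0.0), (0.0, 1.0), BORDER_COLOURS["west"]),
            WallSegment((0.35, 0.0), (0.35, 0.6), INNER_COLOURS["west_wall"]),
            WallSegment((0.65, 0.4), (0.65, 1.0), INNER_COLOURS["east_wall"]),
        ]
        source = OdourSource(location=(0.1, 0.1), scale=1.0, diffusion=0.3)
        return cls(walls=walls, source=source, bounds=(0.0, 1.0, 0.0, 1.0))

    @classmethod
    def open_box(cls, side: float = 1.0) -> "Maze":
        """Square arena with boundary walls only (used as a small fixture)."""
        s = float(side)
        walls = [
            WallSegment((0.0, s), (s, s), BORDER_COLOURS["north"]),
            WallSegment((s, 0.0), (s, s), BORDER_COLOURS["east"]),
            WallSegment((0.0, 0.0), (s, 0.0), BORDER_COLOURS["south"]),
            WallSegment((0.0, 0.0), (0.0, s), BORDER_COLOURS["west"]),
        ]
        source = OdourSource(location=(0.1 * s, 0.1 * s), scale=1.0, diffusion=0.3 * s)
        return cls(walls=walls, source=source, bounds=(0.0, s, 0.0, s))

    # --- geometry helpers -------------------------------------------------
    def contains(self, location) -> bool:
        p = _vec2(location, "location")
        xmin, xmax, ymin, ymax = self.bounds
        return bool(xmin - _EPS <= p[0] <= xmax + _EPS and ymin - _EPS <= p[1] <= ymax + _EPS)

    def _border_index(self, side: str) -> int:
        """Index of the boundary wall on a compass side ('east'/'west'/...)."""
        xmin, xmax, ymin, ymax = self.bounds
        for i, w in enumerate(self.walls):
            x1, y1 = w.p1
            x2, y2 = w.p2
            if side == "east" and np.isclose(x1, xmax) and np.isclose(x2, xmax):
                return i
            if side == "west" and np.isclose(x1, xmin) and np.isclose(x2, xmin):
                return i
            if side == "north" and np.isclose(y1, ymax) and np.isclose(y2, ymax):
                return i
            if side == "south" and np.isclose(y1, ymin) and np.isclose(y2, ymin):
                return i
        raise ValueError(f"maze has no identifiable {side} border wall")

    # --- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "bounds": list(self.bounds),
            "walls": [
                {"p1": w.p1.tolist(), "p2": w.p2.tolist(), "colour": float(w.colour)}
                for w in self.walls
            ],
            "source": {
                "location": self.source.location.tolist(),
                "scale": float(self.source.scale),
                "diffusion": float(self.source.diffusion),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Maze":
        walls = [WallSegment(w["p1"], w["p2"], w["colour"]) for w in d["walls"]]
        src = d["source"]
        return cls(
            walls=walls,
            source=OdourSource(src["location"], src["scale"], src["diffusion"]),
            bounds=tuple(d["bounds"]),
        )

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "Maze":
        path = str(path)
        with open(path) as fh:
            d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_dict(d)


@dataclass
class Observation:
    """One multisensory observation: olfaction, touch, retina, optional speed."""

    o: float
    d: float
    y: np.ndarray
    v_obs: float | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not np.all(np.isfinite(self.y)) or not np.isfinite(self.o) or not np.isfinite(self.d):
            raise ValueError("observation components must be finite")

    @property
    def vector(self) -> np.ndarray:
        parts = [np.array([self.o, self.d]), self.y]
        if self.v_obs is not None:
            parts.append(np.array([self.v_obs]))
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec, P: int, has_speed: bool = False) -> "Observation":
        vec = np.asarray(vec, dtype=float).ravel()
        expect = 2 + P + (1 if has_speed else 0)
        if vec.size != expect:
            raise ValueError(f"expected a {expect}-vector, got size {vec.size}")
        return cls(
            o=float(vec[0]),
            d=float(vec[1]),
            y=vec[2 : 2 + P],
            v_obs=float(vec[2 + P]) if has_speed else None,
        )


def olfactory_signal(source: OdourSource, location) -> float:
    """Olfactory signal at ``location``: ``s * exp(-||location - p_o|| / lam)``.

    Strictly positive, maximal (= ``s``) at the source, and decays
    isotropically with the diffusion length ``lam``.
    """
    p = _vec2(location, "location")
    dist = float(np.linalg.norm(p - source.location))
    return float(source.scale * np.exp(-dist / source.diffusion))


def _ray_segment_intersections(origins, dirs, segs):
    """Vectorised ray/segment intersection.

    origins (N,2), dirs (N,2) unit, segs (W,2,2) -> t (N,W) with inf where
    the ray misses a segment. A graze of a segment endpoint counts as a hit.
    """
    p1 = segs[:, 0, :]  # (W,2)
    e = segs[:, 1, :] - p1  # (W,2)
    # solve origin + t*dir = p1 + s*e  via 2x2 cross products
    dx = dirs[:, None, 0]
    dy = dirs[:, None, 1]
    ex = e[None, :, 0]
    ey = e[None, :, 1]
    denom = dx * ey - dy * ex  # (N,W)
    qx = p1[None, :, 0] - origins[:, None, 0]
    qy = p1[None, :, 1] - origins[:, None, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (qx * ey - qy * ex) / denom
        s = (qx * dy - qy * dx) / denom
    tol = 1e-9
    valid = (np.abs(denom) > _EPS) & (t > tol) & (s >= -tol) & (s <= 1.0 + tol)
    t = np.where(valid, t, np.inf)
    return t


def cast_rays(maze: Maze, origins, angles):
    """Cast many rays at once; returns ``(distances, colours)`` arrays.

    ``origins`` is (N, 2) and ``angles`` (N,). Each ray is intersected with
    every wall and the nearest hit wins (ties at corners resolved by the
    nearest intersection, endpoint grazes count as hits).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    dirs = np.stack([np.cos(angles), -np.sin(angles)], axis=1)
    t = _ray_segment_intersections(origins, dirs, maze._segs)
    idx = np.argmin(t, axis=1)
    dist = t[np.arange(t.shape[0]), idx]
    if not np.all(np.isfinite(dist)):
        raise RuntimeError("ray escaped the maze: geometry is not closed")
    return dist, maze._colours[idx]


def cast_ray(maze: Maze, origin, angle: float):
    """Nearest wall hit along one ray; returns ``(distance, colour)``."""
    p = _vec2(origin, "origin")
    if not maze.contains(p):
        raise ValueError(f"ray origin {p} outside maze bounds {maze.bounds}")
    dist, colour = cast_rays(maze, p[None, :], [float(angle)])
    return float(dist[0]), float(colour[0])


def min_wall_distance(maze: Maze, location) -> float:
    """Minimum Euclidean distance from ``location`` to any wall segment."""
    p = _vec2(location, "location")
    if not maze.contains(p):
        raise ValueError(f"location {p} outside maze bounds {maze.bounds}")
    return float(np.min(_point_segment_distances(p[None, :], maze._segs)))


def _point_segment_distances(points, segs):
    """points (N,2), segs (W,2,2) -> distances (N,W)."""
    p1 = segs[:, 0, :]
    e = segs[:, 1, :] - p1  # (W,2)
    L2 = np.sum(e**2, axis=1)  # (W,)
    q = points[:, None, :] - p1[None, :, :]  # (N,W,2)
    s = np.clip(np.einsum("nwk,wk->nw", q, e) / L2[None, :], 0.0, 1.0)
    proj = p1[None, :, :] + s[..., None] * e[None, :, :]
    return np.linalg.norm(points[:, None, :] - proj, axis=2)


def retinal_angles(P: int = DEFAULT_P) -> np.ndarray:
    """Retinal offsets: ``P`` angles linearly spaced over [-45, +45] degrees."""
    if P < 1:
        raise ValueError("P must be >= 1")
    if P == 1:
        return np.zeros(1)
    return np.linspace(-RETINA_HALF_FOV, RETINA_HALF_FOV, P)


def render_retina(maze: Maze, location, heading: float, P: int = DEFAULT_P) -> np.ndarray:
    """Colour seen by each of ``P`` retinal pixels around ``heading``.

    Pixel ``i`` casts a ray at ``heading + alpha_i`` where the offsets
    ``alpha_i`` span [-45, +45] degrees (pixel 0 at -45 degrees, i.e. the
    counter-clockwise edge of the field of view).
    """
    p = _vec2(location, "location")
    if not maze.contains(p):
        raise ValueError(f"location {p} outside maze bounds {maze.bounds}")
    angles = float(heading) + retinal_angles(P)
    _, colours = cast_rays(maze, np.repeat(p[None, :], P, axis=0), angles)
    return colours


def render_retina_batch(maze: Maze, locations, headings, P: int = DEFAULT_P) -> np.ndarray:
    """Vectorised retina rendering: (N,2) locations, (N,) headings -> (N,P)."""
    locations = np.asarray(locations, dtype=float)
    headings = np.asarray(headings, dtype=float)
    N = locations.shape[0]
    offs = retinal_angles(P)
    origins = np.repeat(locations, P, axis=0)
    angles = (headings[:, None] + offs[None, :]).ravel()
    _, colours = cast_rays(maze, origins, angles)
    return colours.reshape(N, P)


def _check_psd(cov: np.ndarray, name: str = "covariance") -> None:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if np.min(w) < -1e-10:
        raise ValueError(f"{name} is not positive semi-definite (min eig {np.min(w):.3e})")


def sample_gaussian(cov: np.ndarray, rng: np.random.Generator, size=None) -> np.ndarray:
    """Draw from N(0, cov) for any PSD cov (handles singular covariances)."""
    cov = np.asarray(cov, dtype=float)
    w, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    if size is None:
        return L @ rng.standard_normal(cov.shape[0])
    return rng.standard_normal((size, cov.shape[0])) @ L.T


def observe(
    maze: Maze,
    state,
    noise_cov: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    P: int = DEFAULT_P,
    include_speed: bool = False,
) -> Observation:
    """Generate one (possibly noisy) multisensory observation.

    ``state`` is a 4-vector ``(x, y, v, theta)`` or an object exposing it.
    The deterministic part stacks olfaction, touch and the rendered retina
    (plus the speed channel when ``include_speed``); Gaussian noise with the
    given block covariance is added when ``noise_cov`` is supplied.
    """
    x = np.asarray(getattr(state, "vector", state), dtype=float).ravel()
    loc, theta = x[:2], x[3]
    clean = [olfactory_signal(maze.source, loc), min_wall_distance(maze, loc)]
    clean.extend(render_retina(maze, loc, theta, P))
    if include_speed:
        clean.append(x[2])
    clean = np.asarray(clean)
    if noise_cov is not None:
        _check_psd(noise_cov, "observation noise covariance")
        if noise_cov.shape[0] != clean.size:
            raise ValueError(
                f"noise covariance is {noise_cov.shape[0]}x{noise_cov.shape[0]} "
                f"but the observation has {clean.size} channels"
            )
        if rng is None:
            raise ValueError("rng is required when noise_cov is given")
        clean = clean + sample_gaussian(noise_cov, rng)
    return Observation.from_vector(clean, P, has_speed=include_speed)


def swap_border_colours(maze: Maze) -> Maze:
    """Return a maze identical except the east/west border colours exchange.

    Used to construct the second environment for model selection; geometry,
    inner walls and the odour source are untouched, so only vision can tell
    the two environments apart.
    """
    i_e = maze._border_index("east")
    i_w = maze._border_index("west")
    walls = list(maze.walls)
    walls[i_e] = replace(walls[i_e], colour=maze.walls[i_w].colour)
    walls[i_w] = replace(walls[i_w], colour=maze.walls[i_e].colour)
    return Maze(walls=walls, source=maze.source, bounds=maze.bounds)
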