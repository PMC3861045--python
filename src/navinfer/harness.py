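"""Packaged experiments: configuration, seeding, model caching and reports.

`run_experiment` drives the five tasks end to end from a validated
configuration: it trains (and caches) the required sensory models, runs the
task with a single seeded generator, and writes a run directory containing
the config snapshot, a JSON summary and CSV traces. `make_fixtures` builds
the small deterministic objects the test-suite (and exploratory work) uses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dynamics as dyn
from . import envsim, infer, sensemodel, tasks
from .envsim import Maze
from .sensemodel import HDBasis, PlaceBasis, SensoryModel

__all__ = ["ExperimentConfig", "run_experiment", "make_fixtures", "report", "TASK_NAMES"]

TASK_NAMES = ("imagery", "localisation", "decision", "selection", "planning")


@dataclass
class ExperimentConfig:
    """Validated experiment configuration with documented defaults."""

    task: str = "imagery"
    maze: dict | None = None  # Maze.to_dict(); default arena when None
    place_grid: int = 10  # place cells per axis (B = place_grid^2)
    n_hd: int = 32  # head-direction cells
    P: int = 20  # retinal pixels
    beta: float = 10.0  # head-direction sharpness
    dt: float = dyn.DEFAULT_DT
    n_steps: int = dyn.DEFAULT_N_STEPS
    k: float = dyn.DEFAULT_K
    n_loc_side: int = 15  # training locations per axis (225 exemplars)
    n_headings: int = 47  # training headings (x225 = 10,575 exemplars)
    ridge: float = 1e-6
    noise: dict = field(default_factory=lambda: dict(sensemodel.DEFAULT_NOISE))
    path_noise_sd: float = 0.01  # localisation path-integrator noise
    n_trials: int = 50  # localisation trials
    trajectory: str = "SE"  # localisation trajectory
    plan_target: tuple = (0.15, 0.15)  # planning goal (strong olfactory code)
    plan_start: tuple = (0.5, 0.5)  # planning start location
    # decision start sits in the north-east pocket so the goal's approach is
    # in open view (from the centre the inner east wall occludes it)
    decision_start: tuple = (0.72, 0.25)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.task not in TASK_NAMES:
            problems.append(f"task: {self.task!r} not in {TASK_NAMES}")
        for name in ("place_grid", "n_hd", "P", "n_steps", "n_trials", "n_loc_side", "n_headings"):
            if int(getattr(self, name)) < 1:
                problems.append(f"{name}: must be >= 1")
        for name in ("dt", "beta"):
            if getattr(self, name) <= 0:
                problems.append(f"{name}: must be > 0")
        for name in ("k", "ridge", "path_noise_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name}: must be >= 0")
        if self.trajectory.upper() not in ("NE", "NW", "SE", "SW"):
            problems.append(f"trajectory: {self.trajectory!r} not a canonical kind")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"invalid config: unknown fields {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def get_maze(self) -> Maze:
        return Maze.default() if self.maze is None else Maze.from_dict(self.maze)


def _model_cache_key(cfg: ExperimentConfig, maze: Maze, include_speed: bool) -> str:
    payload = json.dumps(
        {
            "maze": maze.to_dict(),
            "place_grid": cfg.place_grid,
            "n_hd": cfg.n_hd,
            "P": cfg.P,
            "beta": cfg.beta,
            "n_loc_side": cfg.n_loc_side,
            "n_headings": cfg.n_headings,
            "ridge": cfg.ridge,
            "noise": cfg.noise,
            "include_speed": include_speed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _trained_model(
    cfg: ExperimentConfig, maze: Maze, include_speed: bool = False, cache_dir=None
) -> SensoryModel:
    key = _model_cache_key(cfg, maze, include_speed)
    if cache_dir is not None:
        path = Path(cache_dir) / f"model-{key}"
        if (path / "manifest.json").exists():
            return SensoryModel.load(path)
    place = PlaceBasis.grid(maze.bounds, cfg.place_grid, cfg.place_grid)
    hd = HDBasis.uniform(cfg.n_hd, cfg.beta)
    model = sensemodel.train_on_environment(
        maze,
        place,
        hd,
        P=cfg.P,
        n_loc_side=cfg.n_loc_side,
        n_headings=cfg.n_headings,
        ridge=cfg.ridge,
        noise=cfg.noise,
        include_speed=include_speed,
    )
    if cache_dir is not None:
        model.save(Path(cache_dir) / f"model-{key}")
    return model


def run_experiment(name: str, config: ExperimentConfig | None = None, seed: int | None = None, out_dir=None) -> tasks.TaskResult:
    """Train what the task needs, run it, and (optionally) write a run dir.

    Deterministic given ``(config, seed)``: a single seeded generator feeds
    every random draw. The run directory contains ``config.yaml``,
    ``summary.json`` and ``traces/*.csv``; trained models are cached there
    under ``models/`` keyed by a content hash of the training inputs.
    """
    if name not in TASK_NAMES:
        raise ValueError(f"unknown experiment {name!r}; valid names: {', '.join(TASK_NAMES)}")
    cfg = config or ExperimentConfig(task=name)
    cfg.task = name
    if seed is not None:
        cfg.seed = int(seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    maze = cfg.get_maze()
    cache_dir = Path(out_dir) / "models" if out_dir is not None else None

    if name == "imagery":
        model = _trained_model(cfg, maze, cache_dir=cache_dir)
        controls, theta0 = dyn.make_canonical_controls(cfg.trajectory, cfg.n_steps, cfg.dt)
        x0 = _centre_state(maze, theta0)
        result = tasks.imagine(maze, model, x0, controls, dt=cfg.dt, k=cfg.k)
    elif name == "localisation":
        model = _trained_model(cfg, maze, cache_dir=cache_dir)
        controls, theta0 = dyn.make_canonical_controls(cfg.trajectory, cfg.n_steps, cfg.dt)
        result = tasks.localise(
            maze,
            model,
            controls=controls,
            x0=_centre_state(maze, theta0),
            path_noise_sd=cfg.path_noise_sd,
            n_trials=cfg.n_trials,
            dt=cfg.dt,
            k=cfg.k,
            rng=rng,
            trajectory=cfg.trajectory,
            seed=cfg.seed,
        )
    elif name == "decision":
        model = _trained_model(cfg, maze, cache_dir=cache_dir)
        c_ne, theta0 = dyn.make_canonical_controls("NE", cfg.n_steps, cfg.dt)
        c_nw, _ = dyn.make_canonical_controls("NW", cfg.n_steps, cfg.dt)
        x0 = np.array([cfg.decision_start[0], cfg.decision_start[1], 0.0, theta0])
        end = dyn.simulate_trajectory(x0, c_ne, dt=cfg.dt, k=cfg.k)[-1]
        goal = envsim.observe(maze, end, P=cfg.P)
        result = tasks.decide(model, x0, [c_ne, c_nw], goal, dt=cfg.dt, k=cfg.k)
    elif name == "selection":
        maze2 = envsim.swap_border_colours(maze)
        model1 = _trained_model(cfg, maze, cache_dir=cache_dir)
        model2 = _trained_model(cfg, maze2, cache_dir=cache_dir)
        controls, theta0 = dyn.make_canonical_controls("NE", cfg.n_steps, cfg.dt)
        x0 = _centre_state(maze, theta0)
        truth = dyn.simulate_trajectory(x0, controls, dt=cfg.dt, k=cfg.k)
        cov = model1.noise_cov()
        obs = [
            envsim.observe(maze, truth[t + 1], noise_cov=cov, rng=rng, P=cfg.P)
            for t in range(cfg.n_steps)
        ]
        result = tasks.select_model([model1, model2], controls, obs, x0, dt=cfg.dt, k=cfg.k)
    else:  # planning
        model = _trained_model(cfg, maze, include_speed=True, cache_dir=cache_dir)
        x0 = np.array([cfg.plan_start[0], cfg.plan_start[1], 0.0, 0.0])
        goal = tasks.make_goal_observation(maze, model, cfg.plan_target, x0=x0)
        result = tasks.plan(
            model,
            x0,
            goal,
            horizon=cfg.n_steps,
            dt=cfg.dt,
            k=cfg.k,
            target_location=cfg.plan_target,
        )
    result.seed = cfg.seed
    result.config.update({k2: v for k2, v in asdict(cfg).items() if v is not None})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(cfg), fh)
        result.save(out)
    return result


def _centre_state(maze: Maze, theta0: float) -> np.ndarray:
    xmin, xmax, ymin, ymax = maze.bounds
    return np.array([0.5 * (xmin + xmax), 0.5 * (ymin + ymax), 0.0, theta0])


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------
def make_fixtures(kind: str, seed: int = 0):
    """Small deterministic fixtures for oracle tests and quick experiments.

    ``toy-lds``: a 2-state/1-observation linear-Gaussian system with 50
    simulated steps. ``mini-maze``: a wall-only square arena.
    ``trained-mini-model``: a 5x5-place / 8-HD-cell model trained on the
    mini maze with an 8-pixel retina.
    """
    rng = np.random.default_rng(seed)
    if kind == "toy-lds":
        A = np.array([[0.9, 0.2], [-0.1, 0.95]])
        B = np.array([[0.0], [0.1]])
        H = np.array([[1.0, 0.5]])
        Q = 0.01 * np.eye(2)
        R = np.array([[0.05]])
        T = 50
        x = rng.normal(0, 1, 2)
        controls = rng.normal(0, 1, (T, 1))
        xs, ys = [], []
        for t in range(T):
            x = A @ x + B @ controls[t] + envsim.sample_gaussian(Q, rng)
            xs.append(x)
            ys.append(H @ x + envsim.sample_gaussian(R, rng))
        return {
            "A": A, "B": B, "H": H, "Q": Q, "R": R,
            "x0_mean": np.zeros(2), "x0_cov": np.eye(2),
            "controls": controls, "states": np.array(xs), "observations": np.array(ys),
        }
    if kind == "mini-maze":
        return Maze.open_box()
    if kind == "trained-mini-model":
        maze = Maze.open_box()
        place = PlaceBasis.grid(maze.bounds, 5, 5)
        hd = HDBasis.uniform(8, beta=4.0)
        return sensemodel.train_on_environment(
            maze, place, hd, P=8, n_loc_side=7, n_headings=12
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


def report(run_dir) -> str:
    """Human-readable headline numbers for a finished run directory."""
    d = Path(run_dir)
    summary_path = d / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"missing {summary_path}")
    payload = json.loads(summary_path.read_text())
    s = payload["summary"]
    lines = [f"task: {payload['task']}  (seed {payload.get('seed')})"]
    if payload["task"] == "localisation":
        lines.append(f"  percent error reduction (intact vs lesioned): {s['percent_error_reduction']:.1f}%")
        lines.append(f"  mean error intact/lesioned/smoothed: "
                     f"{s['mean_error_intact']:.4f} / {s['mean_error_lesioned']:.4f} / {s['mean_error_smoothed']:.4f}")
    elif payload["task"] == "decision":
        lines.append(f"  terminal logLR: {s['terminal_loglr']:.2f}")
        lines.append(f"  first step with |logLR| >= 3: {s['first_step_confident']}")
    elif payload["task"] == "selection":
        lines.append(f"  terminal logLR: {s['terminal_loglr']:.2f}")
        lines.append(f"  per-modality terminal logLR: {s['terminal_decomposition']}")
    elif payload["task"] == "imagery":
        lines.append(f"  central-retina mean R^2: {s['r2_mean_central']:.3f}")
        lines.append(f"  outer-retina mean R^2: {s['r2_mean_outer']:.3f}")
    elif payload["task"] == "planning":
        lines.append(f"  arc length forward/backward: {s['arc_length_forward']:.3f} / {s['arc_length_backward']:.3f}")
        lines.append(f"  replay terminal speed: {s['final_speed_replay']:.3f}")
        if "final_distance_replay" in s:
            lines.append(f"  replay terminal distance to goal: {s['final_distance_replay']:.3f} "
                         f"(coast baseline {s['final_distance_coast']:.3f})")
    return "\n".join(lines)
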