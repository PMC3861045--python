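"""The five spatial-cognition tasks, as thin orchestrations over the model.

All five tasks run inference in the same generative model — a nonlinear
Gaussian state-space model with the agent's dynamics and its learned
multisensory observation model — and differ only in which variables are
observed and which are inferred:

* ``localise``   — filter (and smooth) noisy path integration against
  environmental observations; the "lesioned" variant drops the correction.
* ``imagine``    — run noiseless path integration on virtual commands and
  emit the model's sensory predictions; score them per retinal angle.
* ``decide``     — compare two candidate control sequences by the sequence
  likelihood of a constant goal observation (log likelihood ratio).
* ``select_model`` — compare two environment models on one observation
  sequence by their sequence likelihoods.
* ``plan``       — infer the control sequence that would produce a constant
  goal observation, via the augmented state (+) control model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import dynamics as dyn
from . import envsim, infer
from .envsim import Maze, Observation
from .sensemodel import SensoryModel

__all__ = [
    "TaskResult",
    "loglr_to_probability",
    "localise",
    "imagine",
    "decide",
    "select_model",
    "plan",
    "DECISION_THRESHOLD",
]

#: |logLR| at which a decision is called confident (posterior ~95%)
DECISION_THRESHOLD = 3.0

#: default dynamical noise for the cognition simulations (very low)
DEFAULT_Q_STATE = 1e-8 * np.eye(4)

#: default dynamical noise for planning: essentially noiseless position
#: (so inferred motion must be explained through the control channel) with
#: moderate speed/heading noise that lets the forward sweep explore
DEFAULT_Q_PLAN = np.diag([7e-8, 7e-8, 1e-5, 1e-5])

#: touch variance override used where distance-to-wall is uninformative
TOUCH_DISABLED = 1e6


@dataclass
class TaskResult:
    """Uniform result record: summary scalars plus per-step traces."""

    task: str
    summary: dict
    traces: dict = field(default_factory=dict)
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.summary.items():
            if np.isscalar(v) and not np.all(np.isfinite(v)):
                raise ValueError(f"summary scalar {k!r} is not finite")

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        payload = {
            "task": self.task,
            "seed": self.seed,
            "summary": _jsonify(self.summary),
            "config": _jsonify(self.config),
        }
        (d / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        tdir = d / "traces"
        tdir.mkdir(exist_ok=True)
        for name, arr in self.traces.items():
            df = arr if isinstance(arr, pd.DataFrame) else pd.DataFrame(np.asarray(arr))
            df.to_csv(tdir / f"{name}.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def loglr_to_probability(loglr: float) -> float:
    """Posterior probability of the favoured hypothesis under equal priors.

    ``1 / (1 + exp(-logLR))``; a logLR of 3 corresponds to ~95%.
    """
    if not np.isfinite(loglr):
        raise ValueError("logLR must be finite")
    return float(expit(loglr))


# --------------------------------------------------------------------------
# localisation
# --------------------------------------------------------------------------
def localise(
    maze: Maze,
    model: SensoryModel,
    controls=None,
    x0=None,
    path_noise_sd: float = 0.01,
    n_trials: int = 50,
    dt: float = dyn.DEFAULT_DT,
    k: float = dyn.DEFAULT_K,
    rng: np.random.Generator | None = None,
    trajectory: str = "SE",
    disable_touch: bool = True,
    seed: int | None = None,
) -> TaskResult:
    """Self-localisation with an intact versus lesioned correction step.

    The true path is simulated noiselessly from the maze centre along the
    canonical trajectory. Each trial perturbs the filter's path-integration
    update with per-step Gaussian position noise (sd ``path_noise_sd``) and
    provides noisy environmental observations; the same perturbations and
    observations feed both the intact filter and the lesioned one (pure
    path integration), so the comparison is paired. Touch is disabled by
    default (its variance is raised until it is effectively ignored)
    because distance-to-wall is the same at many locations. The error
    metric is the mean Euclidean distance between true and estimated
    position over the trajectory.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if controls is None:
        controls, theta0 = dyn.make_canonical_controls(trajectory, dt=dt)
    else:
        controls = np.atleast_2d(np.asarray(controls, dtype=float))
        theta0 = x0[3] if x0 is not None else 0.0
    if x0 is None:
        xmin, xmax, ymin, ymax = maze.bounds
        x0 = np.array([0.5 * (xmin + xmax), 0.5 * (ymin + ymax), 0.0, theta0])
    x0 = np.asarray(x0, dtype=float)
    truth = dyn.simulate_trajectory(x0, controls, dt=dt, k=k)
    T = controls.shape[0]

    filt_model = model.with_overrides(sigma_d2=TOUCH_DISABLED) if disable_touch else model
    # clean environmental channels along the true path (computed once)
    clean = np.array(
        [envsim.observe(maze, truth[t + 1], P=model.P).vector for t in range(T)]
    )
    env_cov = model.noise_cov()  # environment generates with the base noise
    Q = np.diag([path_noise_sd**2, path_noise_sd**2, 1e-12, 1e-12])
    transition = infer.AgentTransition(dt=dt, k=k, Q=Q)
    prior = infer.Belief(x0, 1e-10 * np.eye(4))

    errs_intact = np.empty(n_trials)
    errs_lesion = np.empty(n_trials)
    errs_smooth = np.empty(n_trials)
    example = {}
    for trial in range(n_trials):
        noise = np.zeros((T, 4))
        noise[:, :2] = rng.normal(0.0, path_noise_sd, size=(T, 2))
        obs = clean + envsim.sample_gaussian(env_cov, rng, size=T)
        res_int = infer.forward_filter(
            transition, filt_model, prior, controls, obs, predict_mean_noise=noise
        )
        res_les = infer.forward_filter(
            transition, filt_model, prior, controls, obs, lesion=True, predict_mean_noise=noise
        )
        smoothed = infer.backward_smooth(res_int)
        true_pos = truth[1:, :2]
        errs_intact[trial] = np.mean(
            np.linalg.norm(res_int.filtered_means[:, :2] - true_pos, axis=1)
        )
        errs_lesion[trial] = np.mean(
            np.linalg.norm(res_les.filtered_means[:, :2] - true_pos, axis=1)
        )
        errs_smooth[trial] = np.mean(
            np.linalg.norm(np.array([s.mean[:2] for s in smoothed]) - true_pos, axis=1)
        )
        if trial == 0:
            example = {
                "truth": truth[1:],
                "intact": res_int.filtered_means,
                "lesioned": res_les.filtered_means,
                "smoothed": np.array([s.mean for s in smoothed]),
            }
    lesion_mean = errs_lesion.mean()
    reduction = 100.0 * (1.0 - errs_intact.mean() / lesion_mean) if lesion_mean > 1e-12 else 0.0
    return TaskResult(
        task="localisation",
        summary={
            "mean_error_intact": float(errs_intact.mean()),
            "mean_error_lesioned": float(errs_lesion.mean()),
            "mean_error_smoothed": float(errs_smooth.mean()),
            "percent_error_reduction": float(reduction),
            "n_trials": int(n_trials),
            "fraction_trials_intact_better": float(np.mean(errs_intact <= errs_lesion)),
        },
        traces={
            "trial_errors": pd.DataFrame(
                {"intact": errs_intact, "lesioned": errs_lesion, "smoothed": errs_smooth}
            ),
            **{f"example_{k}": v for k, v in example.items()},
        },
        seed=seed,
        config={"path_noise_sd": path_noise_sd, "trajectory": trajectory, "dt": dt, "k": k},
    )


# --------------------------------------------------------------------------
# imagery
# --------------------------------------------------------------------------
def imagine(
    maze: Maze,
    model: SensoryModel,
    x0,
    controls,
    dt: float = dyn.DEFAULT_DT,
    k: float = dyn.DEFAULT_K,
) -> TaskResult:
    """Generate visual imagery along a virtual trajectory and score it.

    Noiseless path integration produces the state sequence; the model's
    predicted retinal input is compared with what the environment would
    actually show, per retinal angle, as the proportion of variance
    explained: ``R^2_p = 1 - SSE_p / SST_p``.
    """
    x0 = np.asarray(getattr(x0, "vector", x0), dtype=float)
    path = dyn.simulate_trajectory(x0, controls, dt=dt, k=k)
    states = path[1:]
    pred = np.array([model.predict_vector(s)[2 : 2 + model.P] for s in states])
    true = envsim.render_retina_batch(maze, states[:, :2], states[:, 3], model.P)
    sse = np.sum((pred - true) ** 2, axis=0)
    sst = np.sum((true - true.mean(axis=0)) ** 2, axis=0)
    # a pixel staring at one wall has zero temporal variance; score such
    # pixels against the scene's mean temporal variance instead, and a
    # fully constant scene by absolute agreement
    floor = 1e-9 * true.shape[0]
    denom = np.where(sst > floor, sst, np.mean(sst))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(
            denom > floor,
            1.0 - sse / np.maximum(denom, floor),
            # no variance anywhere: score against a nominal colour variance
            # of 0.01 (about one wall-colour step squared)
            1.0 - sse / (0.01 * true.shape[0]),
        )
    P = model.P
    n_band = max(1, int(round(0.2 * P)))
    central = np.arange((P - n_band) // 2, (P - n_band) // 2 + n_band)
    outer = np.concatenate([np.arange(n_band // 2 + n_band % 2), P - 1 - np.arange(n_band // 2)])
    return TaskResult(
        task="imagery",
        summary={
            "r2_mean_central": float(np.mean(r2[central])),
            "r2_mean_outer": float(np.mean(r2[outer])),
            "r2_min": float(np.min(r2)),
            "r2_max": float(np.max(r2)),
        },
        traces={
            "r2_per_angle": pd.DataFrame(
                {"retinal_angle": envsim.retinal_angles(P), "r2": r2}
            ),
            "path": path,
            "predicted_retina": pred,
            "true_retina": true,
        },
        config={"dt": dt, "k": k},
    )


# --------------------------------------------------------------------------
# decision making
# --------------------------------------------------------------------------
def _goal_filter(model, transition, x0, controls, goal_vec):
    prior = infer.Belief(np.asarray(x0, dtype=float), 1e-10 * np.eye(4))
    T = np.atleast_2d(controls).shape[0]
    goals = np.repeat(goal_vec[None, :], T, axis=0)
    return infer.forward_filter(transition, model, prior, controls, goals)


def decide(
    model: SensoryModel,
    x0,
    option_controls,
    goal,
    dt: float = dyn.DEFAULT_DT,
    k: float = dyn.DEFAULT_K,
    disable_touch: bool = True,
    Q: np.ndarray | None = None,
) -> TaskResult:
    """Choose between two candidate control sequences by likelihood ratio.

    Each option is forward-filtered against the constant goal observation;
    the log likelihood ratio series is the running difference of the two
    sequence log-likelihoods, with a per-modality decomposition. A decision
    is confident once |logLR| reaches 3 (~95% posterior probability).
    """
    if len(option_controls) != 2:
        raise ValueError("decide expects exactly two option control sequences")
    goal_vec = np.asarray(getattr(goal, "vector", goal), dtype=float).ravel()
    m = model.with_overrides(sigma_d2=TOUCH_DISABLED) if disable_touch else model
    if goal_vec.size != m.n_channels:
        raise ValueError(f"goal has {goal_vec.size} channels, model expects {m.n_channels}")
    transition = infer.AgentTransition(dt=dt, k=k, Q=DEFAULT_Q_STATE if Q is None else Q)
    x0 = np.asarray(getattr(x0, "vector", x0), dtype=float)
    slices = m.modality_slices
    results = [_goal_filter(m, transition, x0, c, goal_vec) for c in option_controls]
    per_series = []
    for res, c in zip(results, option_controls):
        goals = np.repeat(goal_vec[None, :], np.atleast_2d(c).shape[0], axis=0)
        _, per = _per_step_modality(res.predictions, goals, slices)
        per_series.append(per)
    loglr = np.cumsum(results[0].increments) - np.cumsum(results[1].increments)
    decomp = {
        name: np.cumsum(per_series[0][name]) - np.cumsum(per_series[1][name])
        for name in slices
    }
    thr_idx = np.argmax(np.abs(loglr) >= DECISION_THRESHOLD) if np.any(np.abs(loglr) >= DECISION_THRESHOLD) else -1
    return TaskResult(
        task="decision",
        summary={
            "terminal_loglr": float(loglr[-1]),
            "terminal_probability": loglr_to_probability(float(np.clip(loglr[-1], -700, 700))),
            "first_step_confident": int(thr_idx),
            "terminal_decomposition": {k2: float(v[-1]) for k2, v in decomp.items()},
        },
        traces={"loglr": loglr, **{f"loglr_{k2}": v for k2, v in decomp.items()}},
        config={"dt": dt, "k": k},
    )


def _per_step_modality(predictions, observations, slices):
    """Per-step per-modality loglik series (same decomposition as total)."""
    import scipy.linalg as sla

    T = len(predictions)
    per = {name: np.zeros(T) for name in slices}
    total = np.zeros(T)
    for t, (pred, y) in enumerate(zip(predictions, observations)):
        e = np.asarray(y, dtype=float).ravel() - pred.predicted_obs
        L = np.linalg.cholesky(pred.innov_cov)
        z = sla.solve_triangular(L, e, lower=True)
        chan = -0.5 * (z**2 + 2.0 * np.log(np.diag(L)) + np.log(2 * np.pi))
        total[t] = np.sum(chan)
        for name, sl in slices.items():
            per[name][t] = np.sum(chan[sl])
    return total, per


# --------------------------------------------------------------------------
# model selection
# --------------------------------------------------------------------------
def select_model(
    models,
    controls,
    observations,
    x0,
    dt: float = dyn.DEFAULT_DT,
    k: float = dyn.DEFAULT_K,
    Q: np.ndarray | None = None,
) -> TaskResult:
    """Decide which environment the observations came from.

    Runs one forward filter per candidate model on the same observation
    sequence and returns the running log likelihood ratio (model 1 versus
    model 2) with its per-modality decomposition.
    """
    if len(models) != 2:
        raise ValueError("select_model expects exactly two models")
    transition = infer.AgentTransition(dt=dt, k=k, Q=DEFAULT_Q_STATE if Q is None else Q)
    x0 = np.asarray(getattr(x0, "vector", x0), dtype=float)
    prior = infer.Belief(x0, 1e-10 * np.eye(4))
    obs_vecs = [np.asarray(getattr(o, "vector", o), dtype=float).ravel() for o in observations]
    results = [
        infer.forward_filter(transition, m, prior, controls, obs_vecs) for m in models
    ]
    slices = models[0].modality_slices
    per_series = [
        _per_step_modality(res.predictions, obs_vecs, slices)[1] for res in results
    ]
    loglr = np.cumsum(results[0].increments) - np.cumsum(results[1].increments)
    decomp = {
        name: np.cumsum(per_series[0][name]) - np.cumsum(per_series[1][name])
        for name in slices
    }
    return TaskResult(
        task="selection",
        summary={
            "terminal_loglr": float(loglr[-1]),
            "terminal_decomposition": {k2: float(v[-1]) for k2, v in decomp.items()},
        },
        traces={"loglr": loglr, **{f"loglr_{k2}": v for k2, v in decomp.items()}},
        config={"dt": dt, "k": k},
    )


# --------------------------------------------------------------------------
# planning
# --------------------------------------------------------------------------
def make_goal_observation(
    maze: Maze, model: SensoryModel, target, heading: float | None = None, x0=None
) -> Observation:
    """Build the multimodal goal for planning from a target location.

    Olfaction and touch goals are the environment's true values at the
    target; the visual goal is the rendered retina there (facing the
    approach direction from ``x0`` unless a heading is given); the speed
    goal is zero — the agent should be stationary at the target.
    """
    target = np.asarray(target, dtype=float).reshape(2)
    if heading is None:
        if x0 is not None:
            d = target - np.asarray(x0, dtype=float).ravel()[:2]
            heading = float(np.arctan2(-d[1], d[0]))
        else:
            heading = 0.0
    return Observation(
        o=envsim.olfactory_signal(maze.source, target),
        d=envsim.min_wall_distance(maze, target),
        y=envsim.render_retina(maze, target, heading, model.P),
        v_obs=0.0,
    )


def plan(
    model: SensoryModel,
    x0,
    goal,
    horizon: int = dyn.DEFAULT_N_STEPS,
    dt: float = dyn.DEFAULT_DT,
    k: float = dyn.DEFAULT_K,
    Q: np.ndarray | None = None,
    Q_u: np.ndarray | None = None,
    control_prior: infer.ControlEstimate | None = None,
    target_location=None,
) -> TaskResult:
    """Route and motor planning as inference over inputs.

    The goal observation (with a speed channel) is held constant over the
    horizon; forward filtering in the augmented model finds states
    commensurate with the goals and backward smoothing extracts the motor
    commands. The smoothed control means are replayed through the noiseless
    dynamics to score goal attainment (terminal distance to the target and
    terminal speed) against a coast-only baseline.
    """
    if not model.include_speed:
        raise ValueError("planning requires a model with the speed observation channel")
    goal_vec = np.asarray(getattr(goal, "vector", goal), dtype=float).ravel()
    if goal_vec.size != model.n_channels:
        raise ValueError("goal must include olfactory, touch, visual and speed components")
    x0 = np.asarray(getattr(x0, "vector", x0), dtype=float)
    if Q is None:
        Q = DEFAULT_Q_PLAN
    if Q_u is None:
        Q_u = np.diag([0.1, 0.01])  # acceleration drives vary more than turning
    if control_prior is None:
        control_prior = infer.ControlEstimate(np.zeros(2), np.diag([1.0, 0.1]))
    transition = infer.AgentTransition(dt=dt, k=k, Q=np.asarray(Q, dtype=float))
    prior_state = infer.Belief(x0, 1e-8 * np.eye(4))
    goals = np.repeat(goal_vec[None, :], horizon, axis=0)
    result, smoothed, controls_est = infer.infer_inputs(
        model, transition, prior_state, goals, control_prior, Q_u
    )
    fwd = result.filtered_means[:, :4]
    bwd = np.array([s.mean[:4] for s in smoothed])
    u_hat = np.array([c.mean for c in controls_est])
    replay = dyn.simulate_trajectory(x0, u_hat, dt=dt, k=k)
    coast = dyn.simulate_trajectory(x0, np.zeros_like(u_hat), dt=dt, k=k)
    arc_f = float(np.sum(np.linalg.norm(np.diff(fwd[:, :2], axis=0), axis=1)))
    arc_b = float(np.sum(np.linalg.norm(np.diff(bwd[:, :2], axis=0), axis=1)))
    summary = {
        "arc_length_forward": arc_f,
        "arc_length_backward": arc_b,
        "final_speed_replay": float(abs(replay[-1, 2])),
    }
    if target_location is not None:
        tgt = np.asarray(target_location, dtype=float).reshape(2)
        summary["final_distance_replay"] = float(np.linalg.norm(replay[-1, :2] - tgt))
        summary["final_distance_coast"] = float(np.linalg.norm(coast[-1, :2] - tgt))
    return TaskResult(
        task="planning",
        summary=summary,
        traces={
            "forward_path": fwd,
            "backward_path": bwd,
            "controls": u_hat,
            "replay_path": replay,
            "control_sd": np.array([np.sqrt(np.diag(c.cov)) for c in controls_est]),
        },
        config={"dt": dt, "k": k, "horizon": horizon},
    )
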