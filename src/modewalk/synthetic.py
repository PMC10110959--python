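"""Synthetic trajectory generators.

Three migratory modes with the statistical structure the pipeline assumes:

* ``SD`` (slow-diffusive): an anchored, Ornstein-Uhlenbeck-like walk whose
  mean-reverting pull produces heading reversals at multi-minute lags and a
  sub-diffusive long-lag MSD.
* ``SP`` (slow-persistent): a persistent walker whose turn sign alternates
  with high probability, producing zigzag motion around a persistent axis.
* ``FP`` (fast-persistent): a fast persistent walker with small Gaussian
  heading increments.

Default speeds (2.58, 2.21 and 6.27 um/min with spreads 1.90, 1.61 and
2.66) follow the per-mode speed summaries the classifier is meant to
recover.  Mode switching is a first-order Markov chain at one-hour (window)
granularity.  Analytic fixtures (ballistic, Brownian, circular, zigzag,
stationary walkers) with closed-form MSD / shape signatures serve as
oracles in tests.

All generators are deterministic given (params, seed); per-trajectory
streams are derived by counter-based seed splitting so trajectory k is
reproducible in isolation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, SizeError, SpecificationError
from .tracks_io import Trajectory

MODE_NAMES = ("SD", "SP", "FP")
TURN_MODELS = ("anti_persistent", "zigzag", "persistent")

#: Window (minutes) at which mode switching is resolved.
WINDOW_MIN = 60.0


@dataclass(frozen=True)
class ModeParams:
    """Parameters of one migratory mode's walker.

    mean_speed / speed_sd are um/min; turn_scale is radians (the Gaussian
    heading-increment scale for the persistent model, the central zigzag
    turn magnitude for the zigzag model; unused by the anchored model).
    anchor_stiffness (1/min) is the mean-reversion rate of the anchored
    (SD) walk; alt_prob is the per-step probability that the zigzag turn
    sign alternates.
    """

    mode_name: str
    mean_speed: float
    speed_sd: float
    turn_model: str
    turn_scale: float
    anchor_stiffness: float = 0.3
    alt_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.turn_model not in TURN_MODELS:
            raise ConfigurationError(f"unknown turn_model {self.turn_model!r}")
        if not self.mean_speed > 0:
            raise ConfigurationError("mean_speed must be > 0")
        if not (0 < self.turn_scale <= np.pi):
            raise ConfigurationError("turn_scale must lie in (0, pi]")


DEFAULT_MODE_PARAMS: dict[str, ModeParams] = {
    "SD": ModeParams("SD", mean_speed=2.58, speed_sd=1.90,
                     turn_model="anti_persistent", turn_scale=np.pi,
                     anchor_stiffness=0.3),
    "SP": ModeParams("SP", mean_speed=2.21, speed_sd=1.61,
                     turn_model="zigzag", turn_scale=0.9, alt_prob=0.9),
    "FP": ModeParams("FP", mean_speed=6.27, speed_sd=2.66,
                     turn_model="persistent", turn_scale=0.35),
}


@dataclass
class SwitchingConfig:
    """Markov mode-switching configuration at window (1 h) granularity.

    transition_matrix holds row-stochastic per-window transition
    probabilities P_ij (including self-transitions) over (SD, SP, FP);
    initial_distribution the first window's mode law.
    """

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))
    duration: float = 24 * 60.0
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if self.transition_matrix.shape != (3, 3):
            raise ConfigurationError("transition_matrix must be 3x3")
        if (self.transition_matrix < 0).any():
            raise ConfigurationError("transition probabilities must be >= 0")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("transition_matrix rows must sum to 1")
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-12):
            raise ConfigurationError("initial_distribution must sum to 1")


def stream(seed: int, *counters: int) -> np.random.Generator:
    """Counter-split random stream: deterministic given (seed, counters)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, counters)]))


@functools.lru_cache(maxsize=64)
def _truncnorm_location(target_mean: float, sd: float) -> float:
    """Location mu such that a normal(mu, sd) truncated to (0, inf) has the
    requested mean.  Truncation inflates the raw mean, noticeably when
    sd is comparable to the mean, so the location is solved for rather
    than set to the target."""
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    def gap(mu: float) -> float:
        return truncnorm.mean((0.0 - mu) / sd, np.inf, loc=mu, scale=sd) - target_mean

    lo = target_mean - 5.0 * sd
    return float(brentq(gap, lo, target_mean, xtol=1e-12))


def _positive_speeds(rng: np.random.Generator, mean_speed: float, sd: float,
                     n: int) -> np.ndarray:
    """Per-step speeds: truncated normal on (0, inf) with mean ``mean_speed``."""
    mu = _truncnorm_location(mean_speed, sd)
    s = rng.normal(mu, sd, n)
    while (s <= 0).any():
        bad = s <= 0
        s[bad] = rng.normal(mu, sd, int(bad.sum()))
    return s


def _persistent_steps(params: ModeParams, n_steps: int, dt: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Displacement increments of the persistent / zigzag walkers."""
    n = n_steps - 1
    speeds = _positive_speeds(rng, params.mean_speed, params.speed_sd, n)
    heading0 = rng.uniform(-np.pi, np.pi)
    if params.turn_model == "zigzag":
        mags = np.abs(rng.normal(params.turn_scale, params.turn_scale / 3.0, n))
        flips = rng.random(n) < params.alt_prob
        sign0 = rng.choice((-1.0, 1.0))
        signs = sign0 * np.cumprod(np.where(flips, -1.0, 1.0))
        turns = signs * mags
    else:
        turns = rng.normal(0.0, params.turn_scale, n)
    # heading for step i is heading0 plus all turns taken before it
    headings = heading0 + np.concatenate(([0.0], np.cumsum(turns[:-1])))
    return (speeds * dt)[:, None] * np.stack(
        (np.cos(headings), np.sin(headings)), axis=1)


def _anchored_steps(params: ModeParams, n_steps: int, dt: float,
                    rng: np.random.Generator, start: np.ndarray) -> np.ndarray:
    """Increments of the anchored (discrete OU) walk, anchored at ``start``.

    The per-axis noise scale is calibrated so the stationary mean 2D step
    speed equals ``mean_speed``: for x' = (1-k) x + s xi the per-axis step
    s.d. is s * sqrt(2 / (2 - k)), and a 2D Gaussian step of per-axis
    s.d. w has mean length w * sqrt(pi / 2).
    """
    kappa = params.anchor_stiffness * dt
    if not 0 < kappa < 2:
        raise ConfigurationError("anchor_stiffness * dt must lie in (0, 2)")
    sigma = params.mean_speed * dt / np.sqrt(np.pi / 2.0) * np.sqrt((2.0 - kappa) / 2.0)
    n = n_steps - 1
    steps = np.empty((n, 2))
    x = np.zeros(2)  # displacement from anchor
    for i in range(n):
        x_next = (1.0 - kappa) * x + sigma * rng.normal(size=2)
        steps[i] = x_next - x
        x = x_next
    return steps


def _simulate_steps(params: ModeParams, n_steps: int, dt: float,
                    rng: np.random.Generator, start: np.ndarray) -> np.ndarray:
    if params.turn_model == "anti_persistent":
        return _anchored_steps(params, n_steps, dt, rng, start)
    return _persistent_steps(params, n_steps, dt, rng)


def simulate_mode_segment(params: ModeParams, n_steps: int, dt: float = 1.0,
                          seed: int = 0) -> Trajectory:
    """Simulate one constant-mode trajectory of ``n_steps`` points at spacing dt."""
    if n_steps < 2:
        raise SizeError("n_steps must be >= 2")
    rng = stream(seed)
    start = np.zeros(2)
    steps = _simulate_steps(params, n_steps, dt, rng, start)
    positions = np.vstack((start, start + np.cumsum(steps, axis=0)))
    times = np.arange(n_steps, dtype=float) * dt
    return Trajectory(track_id=f"{params.mode_name}-{seed}", times=times,
                      positions=positions, condition=params.mode_name)


def simulate_switching_trajectory(
    mode_params: Mapping[str, ModeParams] | Sequence[ModeParams],
    cfg: SwitchingConfig,
) -> tuple[Trajectory, list[str]]:
    """Simulate a mode-switching trajectory with window-resolved ground truth.

    The mode is held constant within each 60-min window; the window-to-window
    mode is drawn from ``cfg.transition_matrix``.  Only whole windows are
    simulated (a trailing partial window is dropped).  Returns the
    trajectory and the true mode name of each window, in window order.
    """
    if isinstance(mode_params, Mapping):
        params = [mode_params[m] for m in MODE_NAMES]
    else:
        params = list(mode_params)
        if [p.mode_name for p in params] != list(MODE_NAMES):
            raise ConfigurationError("mode_params must cover SD, SP, FP in order")
    n_windows = int(cfg.duration // WINDOW_MIN)
    if n_windows < 1:
        raise SizeError("duration must cover at least one 60-min window")
    steps_per_window = int(round(WINDOW_MIN / cfg.dt))

    chain_rng = stream(cfg.seed, 0)
    states = np.empty(n_windows, dtype=int)
    states[0] = chain_rng.choice(3, p=cfg.initial_distribution)
    for w in range(1, n_windows):
        states[w] = chain_rng.choice(3, p=cfg.transition_matrix[states[w - 1]])

    pos = [np.zeros((1, 2))]
    for w in range(n_windows):
        rng = stream(cfg.seed, 1 + w)
        start = pos[-1][-1]
        steps = _simulate_steps(params[states[w]], steps_per_window + 1, cfg.dt, rng, start)
        pos.append(start + np.cumsum(steps, axis=0))
    positions = np.vstack(pos)
    times = np.arange(positions.shape[0], dtype=float) * cfg.dt
    traj = Trajectory(track_id=f"switch-{cfg.seed}", times=times, positions=positions)
    return traj, [MODE_NAMES[s] for s in states]


def degrade(traj: Trajectory, gap_spec: Sequence[tuple[float, float]],
            seed: int | None = None) -> Trajectory:
    """Remove samples inside gap intervals to emulate tracking dropouts.

    ``gap_spec`` lists (start_min, length_min) intervals; samples with
    start <= t < start + length are dropped.  ``seed`` is accepted for
    interface symmetry with the generators but the operation is
    deterministic.  Intervals must be non-overlapping and lie within the
    trajectory span.
    """
    spans = sorted((float(s), float(s) + float(l)) for s, l in gap_spec)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise SpecificationError("overlapping gap intervals")
    for s, e in spans:
        if s < traj.times[0] - 1e-9 or e > traj.times[-1] + 1e-9:
            raise SpecificationError("gap interval outside trajectory span")
    keep = np.ones(traj.n_points, dtype=bool)
    for s, e in spans:
        keep &= ~((traj.times >= s) & (traj.times < e))
    return Trajectory(track_id=traj.track_id, times=traj.times[keep],
                      positions=traj.positions[keep], condition=traj.condition)


def fixture(kind: str, params: Mapping | None = None, seed: int = 0) -> Trajectory:
    """Analytic fixture trajectories with known statistical signatures.

    kinds: ``ballistic`` (constant-velocity line, MSD = v^2 dt^2),
    ``brownian`` (iid Gaussian increments, MSD slope 1), ``circle``
    (equally spaced points on a circle, asphericity 0), ``zigzag``
    (alternating +/-turn walker, turning-angle variance turn^2) and
    ``stationary``.
    """
    p = dict(params or {})
    dt = float(p.pop("dt", 1.0))
    n = int(p.pop("n_points", 61))
    times = np.arange(n, dtype=float) * dt
    if kind == "ballistic":
        v = float(p.pop("speed", 2.0))
        heading = float(p.pop("heading", 0.0))
        d = np.array([np.cos(heading), np.sin(heading)])
        positions = np.outer(times * v, d)
    elif kind == "brownian":
        sd = float(p.pop("step_sd", 1.0))
        rng = stream(seed)
        steps = rng.normal(0.0, sd * np.sqrt(dt), size=(n - 1, 2))
        positions = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
    elif kind == "circle":
        r = float(p.pop("radius", 10.0))
        phases = 2.0 * np.pi * np.arange(n) / n
        positions = r * np.stack((np.cos(phases), np.sin(phases)), axis=1)
    elif kind == "zigzag":
        v = float(p.pop("speed", 2.0))
        turn = float(p.pop("turn", np.pi / 2.0))
        heading = float(p.pop("heading", 0.0))
        signs = np.where(np.arange(n - 1) % 2 == 0, 1.0, -1.0)
        turns = signs * turn
        headings = heading + np.concatenate(([0.0], np.cumsum(turns[:-1])))
        steps = (v * dt) * np.stack((np.cos(headings), np.sin(headings)), axis=1)
        positions = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
    elif kind == "stationary":
        positions = np.zeros((n, 2))
    else:
        raise ConfigurationError(f"unknown fixture kind {kind!r}")
    if p:
        raise ConfigurationError(f"unknown fixture params {sorted(p)} for kind {kind!r}")
    return Trajectory(track_id=f"{kind}-{seed}", times=times, positions=positions)


def default_segment_pool(
    n_segments: int = 3000,
    seed: int = 0,
    mode_params: Mapping[str, ModeParams] | None = None,
    n_steps: int = 60,
    dt: float = 1.0,
) -> tuple[list[Trajectory], list[str]]:
    """The simulator's default pool of constant-mode one-hour segments.

    Modes are generated in equal proportion (round-robin over SD, SP, FP)
    with the default walker parameters; each segment has its own
    counter-derived stream.  Returns (segments, true mode labels).
    """
    mp = dict(DEFAULT_MODE_PARAMS)
    if mode_params:
        mp.update(mode_params)
    segs: list[Trajectory] = []
    labels: list[str] = []
    for i in range(n_segments):
        mode = MODE_NAMES[i % 3]
        params = mp[mode]
        rng = stream(seed, i)
        start = np.zeros(2)
        steps = _simulate_steps(params, n_steps, dt, rng, start)
        positions = np.vstack((start, start + np.cumsum(steps, axis=0)))
        times = np.arange(n_steps, dtype=float) * dt
        segs.append(Trajectory(track_id=f"{mode}-{i}", times=times,
                               positions=positions, condition=mode))
        labels.append(mode)
    return segs, labels
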