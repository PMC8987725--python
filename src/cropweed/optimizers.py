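"""Swarm minimizers for the transfer head's learning-rate factors.

Two population metaheuristics over a bounded box:

* classic particle swarm optimization (PSO) with a linearly decreasing
  inertia weight, and
* a bat algorithm (BA) whose position update carries a *time factor*
  beta(t) = 1 + sin(pi/2 - pi t / (2 t_max)), decaying from 2 to 1 over the
  run so early moves are amplified (wider exploration) and late moves revert
  to the canonical step (finer exploitation).

Both are generic minimizers: the fitness evaluator is any callable mapping a
position to a scalar to minimize.  For learning-rate tuning the evaluator is
``transfer.fitness_from_factors`` (one minus validation accuracy); the same
machinery runs on analytic test functions.

Conventions
-----------
* Iterations are numbered t = 1..maxiter.  The inertia weight uses the
  completed-iteration count (t-1), so the first PSO step uses omega_max; the
  bat time factor uses t itself, so the final step uses beta = 1 exactly.
* Per-bat random draws follow a fixed order so traces can be scripted:
  frequency uniform, branch uniform, `dim` standard normals (always drawn),
  acceptance uniform.
* The global best is updated from every evaluated candidate (it never
  worsens), while a bat only *moves* to a candidate that improves its own
  fitness and passes the loudness gate.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "PSOConfig",
    "PSOState",
    "BAConfig",
    "BAState",
    "OptimizationResult",
    "inertia_weight",
    "time_factor",
    "pso_step",
    "bat_step",
    "pulse_loudness_update",
    "run_optimizer",
    "consolidate_runs",
]

FitnessEvaluator = Callable[[np.ndarray], float]

#: Default search box for the two learning-rate factors (weight, bias).
DEFAULT_BOUNDS = (0.1, 20.0)


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    """A bounded box; default 2-d for the (weight, bias) factor pair."""

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower=None, upper=None, dimension: int = 2):
        lower = np.full(dimension, DEFAULT_BOUNDS[0]) if lower is None else np.asarray(lower, float)
        upper = np.full(lower.size, DEFAULT_BOUNDS[1]) if upper is None else np.asarray(upper, float)
        if lower.shape != upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dimension))


@dataclasses.dataclass(frozen=True)
class PSOConfig:
    maxiter: int = 20
    m: int = 30
    c1: float = 2.0
    c2: float = 2.0
    omega_max: float = 1.2
    omega_min: float = 0.8
    v_max: float = 2.0
    v_min: float = -2.0

    def __post_init__(self):
        if self.omega_min > self.omega_max:
            raise ValueError("omega_min must be <= omega_max")
        if self.v_min >= self.v_max:
            raise ValueError("v_min must be < v_max")
        if self.m < 1 or self.maxiter < 1:
            raise ValueError("m and maxiter must be >= 1")


@dataclasses.dataclass
class PSOState:
    positions: np.ndarray  # (m, dim)
    velocities: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: np.ndarray
    global_best: np.ndarray
    global_best_fitness: float
    iteration: int = 0


@dataclasses.dataclass(frozen=True)
class BAConfig:
    maxiter: int = 20
    m: int = 10
    f_min: float = -1.0
    f_max: float = 1.0
    r0: float = 0.85  # maximum pulse emission rate
    a0: float = 0.1  # initial loudness
    gamma: float = 0.9  # pulse-rate growth constant
    alpha: float = 0.9  # loudness decay factor
    printed_frequency_form: bool = False  # f_min + (f_max + f_min) * rand

    def __post_init__(self):
        if self.f_min >= self.f_max:
            raise ValueError("f_min must be < f_max")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.m < 1 or self.maxiter < 1:
            raise ValueError("m and maxiter must be >= 1")


@dataclasses.dataclass
class BAState:
    positions: np.ndarray  # (m, dim)
    velocities: np.ndarray
    fitness: np.ndarray  # fitness of each bat's current position
    pulse_rates: np.ndarray
    loudness: np.ndarray
    global_best: np.ndarray
    global_best_fitness: float
    iteration: int = 0


@dataclasses.dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness after each iteration, non-increasing
    seed: int | None
    evaluations: int
    algorithm: str


def inertia_weight(t: int, cfg: PSOConfig) -> float:
    """Linearly decreasing inertia: omega_max at t=0 down to omega_min at
    t=maxiter."""
    if not 0 <= t <= cfg.maxiter:
        raise ValueError(f"t={t} outside [0, {cfg.maxiter}]")
    return cfg.omega_min + (cfg.omega_max - cfg.omega_min) * (cfg.maxiter - t) / cfg.maxiter


def time_factor(t: int, t_max: int) -> float:
    """Bat position-update amplification beta = 1 + sin(pi/2 - pi t/(2 t_max));
    equals 2 at t=0, decays strictly to 1 at t=t_max."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"t={t} outside [0, {t_max}]")
    return 1.0 + math.sin(math.pi / 2.0 - math.pi * t / (2.0 * t_max))


def _evaluate(evaluator: FitnessEvaluator, x: np.ndarray, index: int) -> float:
    try:
        return float(evaluator(x))
    except Exception as exc:  # annotate with the agent index for diagnosis
        raise RuntimeError(f"fitness evaluator failed for agent {index} at {x}") from exc


def init_pso_state(
    space: SearchSpace, cfg: PSOConfig, evaluator: FitnessEvaluator, rng: np.random.Generator
) -> PSOState:
    positions = space.sample(rng, cfg.m)
    velocities = np.zeros_like(positions)
    fitness = np.array([_evaluate(evaluator, x, i) for i, x in enumerate(positions)])
    g = int(np.argmin(fitness))
    return PSOState(
        positions=positions,
        velocities=velocities,
        personal_best=positions.copy(),
        personal_best_fitness=fitness,
        global_best=positions[g].copy(),
        global_best_fitness=float(fitness[g]),
    )


def pso_step(
    state: PSOState,
    cfg: PSOConfig,
    space: SearchSpace,
    evaluator: FitnessEvaluator,
    rng: np.random.Generator,
) -> PSOState:
    """One synchronous PSO iteration.

    v <- omega v + c1 r1 (p_i - x) + c2 r2 (p_g - x), clamped to
    [v_min, v_max]; x <- x + v, clamped to the box; bests updated by fitness
    comparison.  r1, r2 are drawn per particle per dimension.
    """
    omega = inertia_weight(state.iteration, cfg)
    shape = state.positions.shape
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    v = (
        omega * state.velocities
        + cfg.c1 * r1 * (state.personal_best - state.positions)
        + cfg.c2 * r2 * (state.global_best - state.positions)
    )
    v = np.clip(v, cfg.v_min, cfg.v_max)
    x = space.clip(state.positions + v)
    fitness = np.array([_evaluate(evaluator, xi, i) for i, xi in enumerate(x)])

    improved = fitness < state.personal_best_fitness
    personal_best = np.where(improved[:, None], x, state.personal_best)
    personal_best_fitness = np.where(improved, fitness, state.personal_best_fitness)
    g = int(np.argmin(personal_best_fitness))
    if personal_best_fitness[g] < state.global_best_fitness:
        global_best = personal_best[g].copy()
        global_best_fitness = float(personal_best_fitness[g])
    else:
        global_best, global_best_fitness = state.global_best, state.global_best_fitness
    return PSOState(
        positions=x,
        velocities=v,
        personal_best=personal_best,
        personal_best_fitness=personal_best_fitness,
        global_best=global_best,
        global_best_fitness=global_best_fitness,
        iteration=state.iteration + 1,
    )


def init_ba_state(
    space: SearchSpace, cfg: BAConfig, evaluator: FitnessEvaluator, rng: np.random.Generator
) -> BAState:
    positions = space.sample(rng, cfg.m)
    fitness = np.array([_evaluate(evaluator, x, i) for i, x in enumerate(positions)])
    g = int(np.argmin(fitness))
    # Pulse rates start at the t=1 schedule value r0(1 - e^{-gamma}): the
    # t=0 value is 0, which would force the local-walk branch for every bat
    # and leave the velocity/time-factor update unused on early iterations.
    r_init = cfg.r0 * (1.0 - math.exp(-cfg.gamma))
    return BAState(
        positions=positions,
        velocities=np.zeros_like(positions),
        fitness=fitness,
        pulse_rates=np.full(cfg.m, r_init),
        loudness=np.full(cfg.m, cfg.a0),
        global_best=positions[g].copy(),
        global_best_fitness=float(fitness[g]),
    )


def pulse_loudness_update(bat_index: int, state: BAState, cfg: BAConfig, t: int) -> BAState:
    """After an accepted improvement: pulse rate ramps toward r0 as
    r0(1 - e^{-gamma t}) while loudness decays geometrically by alpha."""
    if t < 0:
        raise ValueError("t must be >= 0")
    state.pulse_rates[bat_index] = cfg.r0 * (1.0 - math.exp(-cfg.gamma * t))
    state.loudness[bat_index] = cfg.alpha * state.loudness[bat_index]
    return state


def bat_step(
    state: BAState,
    cfg: BAConfig,
    space: SearchSpace,
    evaluator: FitnessEvaluator,
    rng: np.random.Generator,
    constant_beta: bool = False,
) -> BAState:
    """One BA iteration over all bats (iteration counter t starts at 1).

    Per bat, in draw order: frequency f = f_min + (f_max - f_min) u;
    velocity v += (x - x*) f, clamped to +/- box width; candidate
    x + beta(t) v; with probability (1 - pulse rate) the candidate is
    replaced by a local walk x* + mean-loudness * normal; the bat accepts an
    improving candidate with probability = its loudness (then its pulse rate
    and loudness are updated); the global best absorbs any better candidate.
    """
    t = state.iteration + 1
    beta = 1.0 if constant_beta else time_factor(t, cfg.maxiter)
    dim = space.dimension
    v_cap = space.width
    for i in range(cfg.m):
        u_freq = rng.random()
        span = (cfg.f_max + cfg.f_min) if cfg.printed_frequency_form else (cfg.f_max - cfg.f_min)
        f_i = cfg.f_min + span * u_freq
        u_branch = rng.random()
        walk_noise = rng.standard_normal(dim)
        u_accept = rng.random()

        state.velocities[i] = np.clip(
            state.velocities[i] + (state.positions[i] - state.global_best) * f_i,
            -v_cap,
            v_cap,
        )
        candidate = state.positions[i] + beta * state.velocities[i]
        if u_branch > state.pulse_rates[i]:
            candidate = state.global_best + float(np.mean(state.loudness)) * walk_noise
        candidate = space.clip(candidate)
        f_cand = _evaluate(evaluator, candidate, i)

        if f_cand < state.fitness[i] and u_accept < state.loudness[i]:
            state.positions[i] = candidate
            state.fitness[i] = f_cand
            pulse_loudness_update(i, state, cfg, t)
        if f_cand < state.global_best_fitness:
            state.global_best = candidate.copy()
            state.global_best_fitness = float(f_cand)
    state.iteration = t
    return state


def run_optimizer(
    algorithm: Literal["pso", "ba"],
    space: SearchSpace,
    cfg: PSOConfig | BAConfig | None,
    evaluator: FitnessEvaluator,
    seed: int | None = 0,
) -> OptimizationResult:
    """Run a full optimization; deterministic given the seed.

    Returns the best position/fitness and the per-iteration best-fitness
    history (length ``maxiter``, non-increasing).
    """
    rng = np.random.default_rng(seed)
    evaluations = 0

    def counted(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        return float(evaluator(x))

    history = []
    if algorithm == "pso":
        cfg = cfg or PSOConfig()
        if not isinstance(cfg, PSOConfig):
            raise TypeError("pso requires a PSOConfig")
        state = init_pso_state(space, cfg, counted, rng)
        for _ in range(cfg.maxiter):
            state = pso_step(state, cfg, space, counted, rng)
            history.append(state.global_best_fitness)
        best, best_f = state.global_best, state.global_best_fitness
    elif algorithm == "ba":
        cfg = cfg or BAConfig()
        if not isinstance(cfg, BAConfig):
            raise TypeError("ba requires a BAConfig")
        state = init_ba_state(space, cfg, counted, rng)
        for _ in range(cfg.maxiter):
            state = bat_step(state, cfg, space, counted, rng)
            history.append(state.global_best_fitness)
        best, best_f = state.global_best, state.global_best_fitness
    else:
        raise ValueError(f"unknown algorithm {algorithm!r} (expected 'pso' or 'ba')")

    return OptimizationResult(
        best_position=np.asarray(best, float),
        best_fitness=float(best_f),
        history=np.asarray(history, float),
        seed=seed,
        evaluations=evaluations,
        algorithm=algorithm,
    )


def consolidate_runs(run_bests: Sequence[Sequence[float]]) -> tuple[int, ...]:
    """Consolidate repeated optimization runs into one integer factor pair.

    Each run's best position is rounded to the nearest integer (ties to
    even), the rounded values are averaged across runs, and the average is
    rounded the same way.  E.g. runs (10.2354, 7.6387) and (6.3334, 9.4124)
    consolidate to (8, 8).
    """
    arr = np.asarray(run_bests, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one run")
    if arr.ndim == 1:
        arr = arr[None, :]
    per_run = np.rint(arr)  # numpy rounds half to even
    avg = per_run.mean(axis=0)
    return tuple(int(v) for v in np.rint(avg))
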