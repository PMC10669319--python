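"""Enhanced Pelican Optimization Algorithm (EPOA).

Population-based minimisation modelled on pelican hunting behaviour, with two
enhancements over the base algorithm: the initial population is spread by a
logistic-sine chaotic map instead of i.i.d. uniform draws, and every pelican
attempts a best-guided Lévy-flight jump after the surface-flight phase.

The optimizer is fully deterministic given a seed: one ``numpy`` Generator
drives the run and the sub-draw order is fixed (documented in
:func:`optimize`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "SearchSpace",
    "Pelican",
    "Prey",
    "EPOAConfig",
    "OptimizationResult",
    "ObjectiveError",
    "logistic_step",
    "sine_step",
    "logistic_sine_step",
    "chaotic_stream",
    "init_population_chaotic",
    "init_population_uniform",
    "sample_prey",
    "phase1_update",
    "phase2_update",
    "greedy_accept",
    "levy_sigma_u",
    "levy_steps",
    "levy_step",
    "levy_jump",
    "optimize",
    "save_trace",
]

Objective = Callable[[np.ndarray], float]


class ObjectiveError(RuntimeError):
    """Raised when the user objective fails on a candidate position."""


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained search domain: ``lower[j] < upper[j]`` for all j."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if lower.size < 1:
            raise ValueError("search space needs at least one dimension")
        if not np.all(lower < upper):
            raise ValueError("require lower[j] < upper[j] for every dimension")

    @property
    def dim(self) -> int:
        return int(self.lower.size)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class Pelican:
    """One population member: a position and its objective value."""

    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class Prey:
    """The shared per-iteration target the population moves toward."""

    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class EPOAConfig:
    """Run settings.

    Parameters
    ----------
    pop_size, max_iter
        Population size N (>= 2) and iteration budget T (>= 1).
    R
        Surface-flight neighbourhood constant (0.2 in the base algorithm);
        the local-search radius shrinks as ``R * (1 - t/T)``.
    mu
        Chaos control parameter of the logistic-sine map, in (0, 4].
    beta
        Lévy stability index, in (0, 2); 1.5 is the conventional choice.
    I_choices
        Prey-intensity integers sampled per pelican in phase 1.
    burn_in
        Chaotic-map warm-up iterations discarded before use.
    chaotic_init, levy_jumps
        Ablation switches; with both off the loop is the un-enhanced
        pelican algorithm (uniform init, no Lévy jumps).
    """

    pop_size: int = 30
    max_iter: int = 100
    R: float = 0.2
    mu: float = 2.0
    beta: float = 1.5
    I_choices: tuple[int, ...] = (1, 2)
    burn_in: int = 100
    seed: int | None = None
    chaotic_init: bool = True
    levy_jumps: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.beta < 2.0:
            raise ValueError("beta must lie in (0, 2)")
        if self.R <= 0.0:
            raise ValueError("R must be positive")
        if not 0.0 < self.mu <= 4.0:
            raise ValueError("mu must lie in (0, 4]")
        if len(self.I_choices) == 0:
            raise ValueError("I_choices must be non-empty")


@dataclass
class OptimizationResult:
    """Best solution plus per-iteration bookkeeping."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    evaluations: int
    evaluations_trace: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# chaotic maps


def logistic_step(z: float, mu: float) -> float:
    """One step of the logistic map ``mu * z * (1 - z)``."""
    _check_unit(z)
    return mu * z * (1.0 - z)


def sine_step(z: float) -> float:
    """One step of the sine map ``sin(pi * z)``."""
    _check_unit(z)
    return float(np.sin(np.pi * z))


def logistic_sine_step(z: float, mu: float) -> float:
    """One step of the fused logistic-sine map.

    ``(mu*z*(1-z) + (4-mu)*sin(pi*z)/4) mod 1`` — the blend keeps a wide
    chaotic interval across mu, which is why it is preferred over either
    parent map for population seeding.
    """
    _check_unit(z)
    return (mu * z * (1.0 - z) + (4.0 - mu) * np.sin(np.pi * z) / 4.0) % 1.0


def _check_unit(z: float) -> None:
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"chaotic state must lie in [0, 1], got {z}")


def chaotic_stream(n: int, mu: float, rng: np.random.Generator, burn_in: int = 100) -> np.ndarray:
    """Generate ``n`` logistic-sine values in [0, 1) from one seeded orbit.

    The start point is drawn uniformly, excluding the map's fixed points
    (0, and 0.5 when mu == 4 which maps to 0); ``burn_in`` steps are
    discarded so the orbit forgets its start.
    """
    z = rng.uniform()
    while z == 0.0 or (mu == 4.0 and z == 0.5):  # fixed points collapse the orbit
        z = rng.uniform()
    for _ in range(burn_in):
        z = logistic_sine_step(z, mu)
    out = np.empty(n)
    for i in range(n):
        z = logistic_sine_step(z, mu)
        out[i] = z
    return out


# ---------------------------------------------------------------------------
# population setup


def _evaluate(objective: Objective, x: np.ndarray) -> float:
    try:
        f = float(objective(x))
    except Exception as exc:  # noqa: BLE001 - re-raise with position context
        raise ObjectiveError(f"objective failed at x={x!r}") from exc
    return f


def init_population_chaotic(
    space: SearchSpace, config: EPOAConfig, objective: Objective, rng: np.random.Generator
) -> list[Pelican]:
    """Chaotic initialisation: one logistic-sine stream fills the N x m
    position matrix row-major; coordinates are mapped affinely into the box."""
    n, m = config.pop_size, space.dim
    z = chaotic_stream(n * m, config.mu, rng, config.burn_in).reshape(n, m)
    positions = space.lower + (space.upper - space.lower) * z
    return [Pelican(p, _evaluate(objective, p)) for p in positions]


def init_population_uniform(
    space: SearchSpace, config: EPOAConfig, objective: Objective, rng: np.random.Generator
) -> list[Pelican]:
    """Baseline i.i.d. uniform initialisation (the un-enhanced algorithm)."""
    positions = rng.uniform(space.lower, space.upper, size=(config.pop_size, space.dim))
    return [Pelican(p, _evaluate(objective, p)) for p in positions]


def sample_prey(space: SearchSpace, objective: Objective, rng: np.random.Generator) -> Prey:
    """One uniform in-bounds prey shared by the whole population this iteration."""
    p = rng.uniform(space.lower, space.upper, size=space.dim)
    return Prey(p, _evaluate(objective, p))


# ---------------------------------------------------------------------------
# update phases


def phase1_update(
    x: np.ndarray,
    fitness: float,
    prey: Prey,
    I: int,
    rand: np.ndarray,
    space: SearchSpace,
) -> np.ndarray:
    """Prey-approach move: advance toward better prey, retreat from worse."""
    x = np.asarray(x, dtype=float)
    rand = np.asarray(rand, dtype=float)
    if x.shape != rand.shape or x.shape != prey.position.shape:
        raise ValueError("x, rand and prey position must share one shape")
    if prey.fitness < fitness:
        cand = x + rand * (prey.position - I * x)
    else:
        cand = x + rand * (x - prey.position)
    return space.clip(cand)


def phase2_update(
    x: np.ndarray, t: int, T: int, R: float, rand: np.ndarray, space: SearchSpace
) -> np.ndarray:
    """Surface-flight move: local perturbation within a shrinking radius
    ``R * (1 - t/T)`` around the current position."""
    if t > T:
        raise ValueError(f"iteration t={t} exceeds the budget T={T}")
    x = np.asarray(x, dtype=float)
    rand = np.asarray(rand, dtype=float)
    cand = x + R * (1.0 - t / T) * (2.0 * rand - 1.0) * x
    return space.clip(cand)


def greedy_accept(current: Pelican, candidate_position: np.ndarray, objective: Objective) -> Pelican:
    """Accept the candidate iff it is strictly better; ties keep the incumbent."""
    f = _evaluate(objective, candidate_position)
    if f < current.fitness:
        return Pelican(np.asarray(candidate_position, dtype=float).copy(), f)
    return current


# ---------------------------------------------------------------------------
# Lévy flight (Mantegna algorithm)


def levy_sigma_u(beta: float) -> float:
    """Mantegna scale: sigma_u = [ Gamma(1+b) sin(pi b/2) /
    (Gamma((1+b)/2) * b * 2^((b-1)/2)) ]^(1/b)."""
    if not 0.0 < beta < 2.0:
        raise ValueError("beta must lie in (0, 2)")
    num = _gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_steps(beta: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """``size`` heavy-tailed steps s = u / |v|^(1/beta), u ~ N(0, sigma_u^2),
    v ~ N(0, 1); the u vector is drawn before the v vector."""
    sigma = levy_sigma_u(beta)
    u = rng.normal(0.0, sigma, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / beta)


def levy_step(beta: float, rng: np.random.Generator) -> float:
    """Single Mantegna Lévy step."""
    return float(levy_steps(beta, rng, 1)[0])


def levy_jump(
    pelican: Pelican,
    x_best: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    objective: Objective,
    space: SearchSpace,
) -> Pelican:
    """Best-guided Lévy jump, greedily accepted against the pelican's
    post-phase-2 state.

    Per coordinate j the Mantegna step s_j is the Lévy draw and the move is
    ``x_j + 0.01 * s_j * (x_j - xbest_j)``; at the incumbent best the scale
    vanishes and the position is unchanged.
    """
    x = pelican.position
    s = levy_steps(beta, rng, x.size)
    cand = space.clip(x + 0.01 * s * (x - np.asarray(x_best, dtype=float)))
    return greedy_accept(pelican, cand, objective)


# ---------------------------------------------------------------------------
# main loop


def optimize(objective: Objective, space: SearchSpace, config: EPOAConfig) -> OptimizationResult:
    """Run EPOA and return the best solution found.

    Draw order (one Generator, seeded from ``config.seed``): the init stream
    (chaotic start point, or the uniform position block), then per iteration
    the prey position, then per pelican: the intensity I, the phase-1 rand
    vector, the phase-2 rand vector, and (if enabled) the m Lévy pairs.
    Greedy acceptance after every move makes the best-fitness trace monotone
    non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    n_eval = 0

    def counted(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return _evaluate(objective, x)

    if config.chaotic_init:
        pop = init_population_chaotic(space, config, counted, rng)
    else:
        pop = init_population_uniform(space, config, counted, rng)

    best = min(pop, key=lambda p: p.fitness)
    T = config.max_iter
    trace = np.empty(T)
    eval_trace = np.empty(T, dtype=int)

    for t in range(1, T + 1):
        prey = sample_prey(space, counted, rng)
        if prey.fitness < best.fitness:
            best = Pelican(prey.position.copy(), prey.fitness)
        for i, pel in enumerate(pop):
            I = int(rng.choice(config.I_choices))
            cand = phase1_update(pel.position, pel.fitness, prey, I, rng.random(space.dim), space)
            pel = greedy_accept(pel, cand, counted)
            cand = phase2_update(pel.position, t, T, config.R, rng.random(space.dim), space)
            pel = greedy_accept(pel, cand, counted)
            if config.levy_jumps:
                pel = levy_jump(pel, best.position, config.beta, rng, counted, space)
            pop[i] = pel
            if pel.fitness < best.fitness:
                best = pel
        trace[t - 1] = best.fitness
        eval_trace[t - 1] = n_eval

    return OptimizationResult(
        best_position=best.position.copy(),
        best_fitness=float(best.fitness),
        trace=trace,
        evaluations=n_eval,
        evaluations_trace=eval_trace,
    )


def save_trace(result: OptimizationResult, path) -> None:
    """Write the convergence trace as CSV: iteration, best_fitness, evaluations."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "best_fitness", "evaluations"])
        for i, (f, e) in enumerate(zip(result.trace, result.evaluations_trace), start=1):
            w.writerow([i, repr(float(f)), int(e)])
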