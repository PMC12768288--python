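"""Kepler Optimization Algorithm (KOA) for bounded mixed search spaces.

A population metaheuristic in which candidate solutions are planets and
the incumbent best is the Sun. Each generation every planet takes one of
two moves:

* an **orbital** move — the planet drifts with a velocity term and is
  pulled toward the Sun by a gravity-plus-random coefficient::

      X_i(t+1) = X_i(t) + F·V_i(t) + (Fg_i(t) + |r|) · U ⊙ (X_S − X_i(t))

* a **distance-adaptive** move — the planet contracts toward (or, when
  the regulating parameter h is large, expands around) the centroid of
  itself, the Sun and a random peer::

      X_i(t+1) = X_i(t)⊙U₁ + (1−U₁)⊙(M + h·(M − X_b)),
      M = (X_i(t) + X_S + X_a(t)) / 3

The published description of this optimizer fixes only the two update
equations and the roles of the symbols; the generating rules used here
(fitness-derived planet masses, exponentially decaying gravity constant,
velocity built from a random planet pair plus decaying jitter, Bernoulli
masks U/U₁, the h schedule, and an h-tied choice between the two moves)
are this package's own, exposed as :class:`KOAConfig` fields so the
mechanics are auditable and overridable. Planets only accept improving
moves and the Sun is elitist, so the best-fitness history never
increases. Positions are clamped to the bounds after every move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Parameter",
    "SearchSpace",
    "Planet",
    "KOAConfig",
    "KOAState",
    "initialize_population",
    "orbital_position_update",
    "distance_adaptive_update",
    "optimize",
    "decode_hyperparameters",
]


# --------------------------------------------------------------------------- #
# search space
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Parameter:
    name: str
    lower: float
    upper: float
    kind: str = "continuous"  # "continuous" | "integer"

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"{self.name}: kind must be continuous or integer")


@dataclass(frozen=True)
class SearchSpace:
    parameters: tuple[Parameter, ...]

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("search space must contain at least one parameter")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @property
    def dim(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def lower(self) -> np.ndarray:
        return np.array([p.lower for p in self.parameters], dtype=float)

    def upper(self) -> np.ndarray:
        return np.array([p.upper for p in self.parameters], dtype=float)

    def clamp(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower(), self.upper())


def space_from_dict(ranges: dict[str, tuple[float, float, str]]) -> SearchSpace:
    return SearchSpace(tuple(Parameter(n, lo, hi, kind) for n, (lo, hi, kind) in ranges.items()))


def decode_hyperparameters(position: np.ndarray, space: SearchSpace) -> dict[str, float | int]:
    """Map a position to named parameters; integer dims round to nearest."""
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dim,):
        raise ValueError(f"position has shape {position.shape}, space dim is {space.dim}")
    lo, hi = space.lower(), space.upper()
    if np.any(position < lo) or np.any(position > hi):
        raise ValueError("position outside the search-space bounds")
    out: dict[str, float | int] = {}
    for j, p in enumerate(space.parameters):
        if p.kind == "integer":
            out[p.name] = int(np.clip(round(position[j]), p.lower, p.upper))
        else:
            out[p.name] = float(position[j])
    return out


# --------------------------------------------------------------------------- #
# state
# --------------------------------------------------------------------------- #

@dataclass
class Planet:
    position: np.ndarray
    velocity: np.ndarray
    fitness: float = np.inf


@dataclass
class KOAConfig:
    population_size: int = 10
    max_iterations: int = 50
    seed: int | None = None
    gravity_initial: float = 0.1      # μ0 in μ(t) = μ0·exp(−γ·t/T)
    gravity_decay: float = 15.0       # γ
    eccentricity_range: tuple[float, float] = (0.0, 1.0)
    h_scale: float = 1.0              # h(t) envelope = h_scale·exp(−η·t/T)
    h_decay: float = 4.0              # η
    mask_prob: float = 0.5            # P(U element = 1); U₁ uses 1 − exploitation bias
    jitter_scale: float = 0.05        # residual exploration, fraction of span
    jitter_decay: float = 6.0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class KOAState:
    planets: list[Planet]
    sun_position: np.ndarray
    sun_fitness: float
    iteration: int = 0
    history: list[float] = field(default_factory=list)


def _safe_eval(objective, position: np.ndarray) -> float:
    val = float(objective(position))
    if not np.isfinite(val):
        warnings.warn("objective returned a non-finite value; treated as +inf")
        return np.inf
    return val


def initialize_population(
    space: SearchSpace, config: KOAConfig, rng: np.random.Generator, objective=None
) -> KOAState:
    """Uniform positions within bounds, zero velocities, elitist Sun."""
    lo, hi = space.lower(), space.upper()
    planets = []
    for _ in range(config.population_size):
        pos = lo + rng.random(space.dim) * (hi - lo)
        planets.append(Planet(pos, np.zeros(space.dim)))
    if objective is not None:
        for p in planets:
            p.fitness = _safe_eval(objective, p.position)
    best = min(planets, key=lambda p: p.fitness)
    return KOAState(planets, best.position.copy(), best.fitness)


# --------------------------------------------------------------------------- #
# the two published position updates (literal element-wise forms)
# --------------------------------------------------------------------------- #

def orbital_position_update(
    position: np.ndarray,
    velocity: np.ndarray,
    sun_position: np.ndarray,
    F: float,
    Fg: float,
    r: float,
    U: np.ndarray,
) -> np.ndarray:
    position = np.asarray(position, float)
    velocity = np.asarray(velocity, float)
    sun_position = np.asarray(sun_position, float)
    U = np.asarray(U, float)
    if not (position.shape == velocity.shape == sun_position.shape == U.shape):
        raise ValueError("orbital update: vector dimensions disagree")
    return position + F * velocity + (Fg + abs(r)) * U * (sun_position - position)


def distance_adaptive_update(
    position: np.ndarray,
    sun_position: np.ndarray,
    x_a: np.ndarray,
    x_b: np.ndarray,
    U1: np.ndarray,
    h: float,
) -> np.ndarray:
    position = np.asarray(position, float)
    sun_position = np.asarray(sun_position, float)
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    U1 = np.asarray(U1, float)
    if not (position.shape == sun_position.shape == x_a.shape == x_b.shape == U1.shape):
        raise ValueError("distance-adaptive update: vector dimensions disagree")
    mean = (position + sun_position + x_a) / 3.0
    return position * U1 + (1.0 - U1) * (mean + h * (mean - x_b))


# --------------------------------------------------------------------------- #
# the optimizer
# --------------------------------------------------------------------------- #

def optimize(
    objective,
    space: SearchSpace,
    config: KOAConfig = KOAConfig(),
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over ``space``; returns (best x, best f, history).

    ``history[t]`` is the incumbent best after generation t+1 and is
    non-increasing by construction (greedy planet acceptance + elitist Sun).
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_population(space, config, rng, objective)
    lo, hi = space.lower(), space.upper()
    span = hi - lo
    T = config.max_iterations
    ecc = rng.uniform(*config.eccentricity_range, size=config.population_size)
    diag = float(np.linalg.norm(span))

    for t in range(1, T + 1):
        frac = t / T
        mu = config.gravity_initial * np.exp(-config.gravity_decay * frac)
        h_env = config.h_scale * np.exp(-config.h_decay * frac)
        # large h ⇒ exploration (distance-adaptive move); small h ⇒ orbital pull
        p_orbital = 1.0 / (1.0 + h_env)
        jitter_sd = config.jitter_scale * np.exp(-config.jitter_decay * frac)
        fits = np.array([p.fitness for p in state.planets])
        worst = fits[np.isfinite(fits)].max() if np.isfinite(fits).any() else 1.0
        best = state.sun_fitness
        denom = (worst - best) or 1.0

        for i, planet in enumerate(state.planets):
            others = [j for j in range(config.population_size) if j != i]
            a_idx, b_idx = rng.choice(others, size=2, replace=(len(others) < 2))
            x_a = state.planets[a_idx].position
            x_b = state.planets[b_idx].position
            velocity = rng.random() * (x_a - x_b) + jitter_sd * span * rng.standard_normal(space.dim)

            if rng.random() < p_orbital:
                mass = (worst - planet.fitness) / denom if np.isfinite(planet.fitness) else 0.0
                R = np.linalg.norm(state.sun_position - planet.position) / (diag or 1.0)
                Fg = ecc[i] * mu * mass / (R**2 + 1e-8)
                Fg = min(Fg, 1.0)
                F = 1.0 if rng.random() < 0.5 else -1.0
                r = rng.random()
                U = (rng.random(space.dim) < config.mask_prob).astype(float)
                candidate = orbital_position_update(
                    planet.position, velocity, state.sun_position, F, Fg, r, U
                )
            else:
                h = h_env * rng.standard_normal()
                U1 = (rng.random(space.dim) < config.mask_prob).astype(float)
                candidate = distance_adaptive_update(
                    planet.position, state.sun_position, x_a, x_b, U1, h
                )

            candidate = np.clip(candidate, lo, hi)
            fit = _safe_eval(objective, candidate)
            if fit < planet.fitness:  # greedy per-planet acceptance
                planet.position = candidate
                planet.velocity = velocity
                planet.fitness = fit
                if fit < state.sun_fitness:  # elitist Sun
                    state.sun_fitness = fit
                    state.sun_position = candidate.copy()

        state.iteration = t
        state.history.append(state.sun_fitness)

    return state.sun_position, state.sun_fitness, np.asarray(state.history)
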