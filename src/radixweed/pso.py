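"""Particle swarm search for the shortest clearance-feasible arch trajectory.

The decision variables are the two Bezier control offsets (alpha, beta),
bounded by [0, 0.8*h2] x [0, 0.8*(w1+w2)].  The velocity update is the
classic inertia/cognitive/social rule; the position step is additionally
scaled by an adaptive factor r(n) = 1 - tanh(n / (1 + n_max)) that shrinks
the search range as iterations accumulate.  Trajectories that violate the
crop clearance are penalised rather than rejected, which keeps the swarm
dynamics total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import (
    ArchTrajectory,
    CropObstacle,
    PlanarPoint,
    TrajectoryParams,
    alpha_bound,
    beta_bound,
    build_arch,
    check_clearance,
    path_length,
)

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "Scene",
    "OptResult",
    "adaptive_factor",
    "init_swarm",
    "swarm_step",
    "optimize_transition",
    "grid_oracle",
    "scene_fitness",
]

Fitness = Callable[[float, float], float]


@dataclass(frozen=True)
class SwarmConfig:
    n_particles: int = 5
    n_max: int = 200
    omega: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    seed: int | None = None
    penalty: float = 1e6  # mm added to the fitness of infeasible trajectories

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_max < 1:
            raise ValueError("need at least one particle and one iteration")
        if min(self.omega, self.c1, self.c2) <= 0:
            raise ValueError("omega, c1, c2 must be positive")


@dataclass
class SwarmState:
    """Mutable swarm: positions/velocities are (n_particles, 2) arrays."""

    pos: np.ndarray
    vel: np.ndarray
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    bounds: np.ndarray  # (2, 2): [[a_lo, a_hi], [b_lo, b_hi]]
    iteration: int
    rng: np.random.Generator = field(repr=False)


def adaptive_factor(n: int, n_max: int) -> float:
    """Position-update shrink factor r = 1 - tanh(n / (1 + n_max)).

    r(0) = 1 and r decreases strictly with n, so early iterations explore
    with full steps and late ones refine locally.
    """
    if n < 0:
        raise ValueError("iteration index must be non-negative")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    return 1.0 - math.tanh(n / (1.0 + n_max))


def init_swarm(fitness: Fitness, bounds: Sequence[Sequence[float]], cfg: SwarmConfig) -> SwarmState:
    """Particles uniform over the bounded box, velocities zero."""
    rng = np.random.default_rng(cfg.seed)
    b = np.asarray(bounds, dtype=float)
    pos = rng.uniform(b[:, 0], b[:, 1], size=(cfg.n_particles, 2))
    fit = np.array([fitness(a, be) for a, be in pos])
    i_best = int(np.argmin(fit))
    return SwarmState(
        pos=pos,
        vel=np.zeros_like(pos),
        pbest_pos=pos.copy(),
        pbest_fit=fit.copy(),
        gbest_pos=pos[i_best].copy(),
        gbest_fit=float(fit[i_best]),
        bounds=b,
        iteration=0,
        rng=rng,
    )


def swarm_step(state: SwarmState, cfg: SwarmConfig, fitness: Fitness) -> SwarmState:
    """One synchronous swarm update (in place; returns the same state).

    v <- w*v + c1*R1*(pbest - x) + c2*R2*(gbest - x)
    x <- x + r(n)*v, then clipped to bounds (velocity component zeroed where
    a particle hit a bound).
    """
    r1 = state.rng.uniform(size=state.pos.shape)
    r2 = state.rng.uniform(size=state.pos.shape)
    state.vel = (
        cfg.omega * state.vel
        + cfg.c1 * r1 * (state.pbest_pos - state.pos)
        + cfg.c2 * r2 * (state.gbest_pos - state.pos)
    )
    r = adaptive_factor(state.iteration, cfg.n_max)
    raw = state.pos + r * state.vel
    lo, hi = state.bounds[:, 0], state.bounds[:, 1]
    clipped = np.clip(raw, lo, hi)
    state.vel[raw != clipped] = 0.0
    state.pos = clipped

    fit = np.array([fitness(a, b) for a, b in state.pos])
    improved = fit < state.pbest_fit
    state.pbest_pos[improved] = state.pos[improved]
    state.pbest_fit[improved] = fit[improved]
    i_best = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[i_best] < state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[i_best])
        state.gbest_pos = state.pbest_pos[i_best].copy()
    state.iteration += 1
    return state


@dataclass(frozen=True)
class Scene:
    """A planning scene in plane N: endpoints, one crop cylinder, arch dims."""

    s: PlanarPoint
    e: PlanarPoint
    obstacle: CropObstacle
    params: TrajectoryParams

    @property
    def bounds(self) -> np.ndarray:
        return np.array(
            [[0.0, alpha_bound(self.params)], [0.0, beta_bound(self.obstacle)]]
        )


def scene_fitness(scene: Scene, cfg: SwarmConfig) -> Fitness:
    """Penalised path length of the arch built from (alpha, beta)."""

    def fit(alpha: float, beta: float) -> float:
        traj = build_arch(scene.s, scene.e, scene.obstacle, scene.params, alpha, beta)
        length = path_length(traj)
        rep = check_clearance(traj, scene.obstacle, scene.params.clearance_margin)
        return length if rep.feasible else length + cfg.penalty

    return fit


@dataclass(frozen=True)
class OptResult:
    alpha: float
    beta: float
    fitness: float
    trajectory: ArchTrajectory
    history: np.ndarray  # gbest fitness per iteration, length n_max
    feasible: bool
    min_margin: float


def optimize_transition(scene: Scene, cfg: SwarmConfig) -> OptResult:
    """Run the swarm on a scene and return the best feasible arch.

    Raises RuntimeError if no clearance-feasible trajectory was found after
    n_max iterations (the fitness of every visited point carried the
    infeasibility penalty).
    """
    if scene.params.apex <= scene.obstacle.height_h3:
        raise ValueError("infeasible scene: apex does not exceed obstacle height")
    fit = scene_fitness(scene, cfg)
    state = init_swarm(fit, scene.bounds, cfg)
    history = np.empty(cfg.n_max)
    for i in range(cfg.n_max):
        swarm_step(state, cfg, fit)
        history[i] = state.gbest_fit

    alpha, beta = (float(v) for v in state.gbest_pos)
    traj = build_arch(scene.s, scene.e, scene.obstacle, scene.params, alpha, beta)
    rep = check_clearance(traj, scene.obstacle, scene.params.clearance_margin)
    if not rep.feasible:
        raise RuntimeError(
            "no clearance-feasible trajectory found: best (alpha, beta) = "
            f"({alpha:.3f}, {beta:.3f}), margin deficit {rep.min_margin:.3f} mm"
        )
    return OptResult(
        alpha=alpha,
        beta=beta,
        fitness=path_length(traj),
        trajectory=traj,
        history=history,
        feasible=True,
        min_margin=rep.min_margin,
    )


def grid_oracle(scene: Scene, resolution: int = 40, cfg: SwarmConfig | None = None):
    """Exhaustive grid argmin of the penalised fitness (test oracle).

    Returns ((alpha, beta), fitness) at the best of resolution^2 grid nodes.
    """
    if resolution < 20:
        raise ValueError("resolution must be >= 20 points per axis")
    cfg = cfg or SwarmConfig()
    fit = scene_fitness(scene, cfg)
    b = scene.bounds
    alphas = np.linspace(b[0, 0], b[0, 1], resolution)
    betas = np.linspace(b[1, 0], b[1, 1], resolution)
    best = (math.inf, 0.0, 0.0)
    for a in alphas:
        for be in betas:
            f = fit(a, be)
            if f < best[0]:
                best = (f, float(a), float(be))
    return (best[1], best[2]), best[0]
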