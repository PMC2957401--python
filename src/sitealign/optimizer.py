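"""Global and local optimizers over the space of rigid transforms.

``run_crs`` implements a controlled random search (CRS): a population of M
candidate transforms, sampled over the feasible domain Θ, is iteratively
contracted by replacing the population's worst member with a weighted
reflection of the weighted centroid of N+1 randomly drawn members onto the
worst of the drawn points.  The quaternion part of every trial point is
renormalized to the unit sphere, so population members always encode valid
rotations.  The search stops when the population's objective spread
``g_max - g_min`` falls below ``epsilon`` or the evaluation budget runs out.
CRS needs no derivatives, which matters here: both alignment objectives are
non-smooth (Lipschitz) in the transform.

``run_icp`` is the classic Iterative Closest Point local baseline: alternate
the closest-point mapping with the closed-form optimal transform for that
mapping.  Its fixed point depends on the initial relative positioning of the
two clouds, which is precisely the failure mode the global search avoids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .correspondence import closest_point_mapping, mean_square_error
from .errors import DegenerateCandidateError, InvalidArgumentError
from .geometry import (
    SearchDomain,
    TransformVector,
    normalize_candidate,
    optimal_transform_for_mapping,
    random_transform,
)

logger = logging.getLogger(__name__)

#: search-space dimension: 3 rotational + 3 translational degrees of freedom
N_DIM = 6


@dataclass
class CRSConfig:
    """Tunables of the controlled random search.

    M defaults to 25·N = 150: large enough for the population to see the
    global basin, small enough not to stall convergence.  ``epsilon`` is the
    absolute stopping tolerance on g_max - g_min (Å²); ``alpha0`` the initial
    reflection parameter.
    """

    M: int = 25 * N_DIM
    epsilon: float = 1e-4
    alpha0: float = 0.9
    max_evals: int = 20_000
    seed: int = 0
    weighted_centroid: bool = True
    include_best: bool = False
    relative_spread: bool = False

    N: int = field(default=N_DIM, init=False)

    def __post_init__(self):
        if self.M < 10 * N_DIM:
            raise InvalidArgumentError(f"population size M={self.M} too small (need >= {10 * N_DIM})")
        if not (0.0 < self.alpha0 < 1.0):
            raise InvalidArgumentError("alpha0 must lie in (0, 1)")
        if self.epsilon <= 0.0:
            raise InvalidArgumentError("epsilon must be positive")
        if self.max_evals <= self.M:
            raise InvalidArgumentError("max_evals must exceed the population size M")


@dataclass
class CRSPopulation:
    """The set S of candidate transforms with cached objective values."""

    points: list[TransformVector]
    values: np.ndarray
    eval_count: int = 0

    @property
    def g_max(self) -> float:
        return float(self.values.max())

    @property
    def g_min(self) -> float:
        return float(self.values.min())

    def spread(self) -> float:
        return self.g_max - self.g_min

    def best(self) -> tuple[TransformVector, float]:
        i = int(np.argmin(self.values))
        return self.points[i], float(self.values[i])


@dataclass
class CRSResult:
    best: TransformVector
    g_best: float
    converged: bool
    eval_count: int
    trace: list[tuple[int, float, float]]  # (eval_count, g_min, g_max)


_MAX_RETRIES = 100


def initialize_population(
    objective: Callable[[TransformVector], float],
    domain: SearchDomain,
    config: CRSConfig,
    rng: np.random.Generator,
) -> CRSPopulation:
    """Sample M transforms over Θ and evaluate the objective on each."""
    from .errors import SiteAlignError

    points: list[TransformVector] = []
    values = np.empty(config.M)
    for i in range(config.M):
        for _ in range(_MAX_RETRIES):
            a = random_transform(domain, rng)
            try:
                v = objective(a)
            except SiteAlignError:
                # structural (deterministic) failure: retrying cannot help
                raise
            except Exception:
                continue
            if np.isfinite(v):
                points.append(a)
                values[i] = v
                break
        else:
            raise InvalidArgumentError(
                "objective failed repeatedly during population initialization"
            )
    return CRSPopulation(points, values, eval_count=config.M)


def update_alpha(
    alpha0: float, iteration: int, M: int, spread: float, spread0: float
) -> float:
    """Reflection parameter schedule.

    Shrinks with both the iteration count and the ratio of the current to the
    initial objective spread, so trial points reduce to (near-)centroids as
    the population clusters around a minimum.  The decay is deliberately
    slow (tenth-root of the spread ratio, iteration scale 50·M): aggressive
    schedules freeze the reflection too early and the population collapses
    onto a local minimum before the global basin is found.
    """
    if spread0 <= 0.0:
        ratio = 0.0
    else:
        ratio = min(1.0, max(0.0, spread / spread0))
    return alpha0 * ratio**0.1 / (1.0 + iteration / (50.0 * M))


def crs_step(
    pop: CRSPopulation,
    objective: Callable[[TransformVector], float],
    config: CRSConfig,
    rng: np.random.Generator,
    alpha: float,
) -> bool:
    """One search/update cycle; returns True if the population improved.

    Draw N+1 distinct members; form their weighted centroid a_c (weights
    favour low objective values); reflect over the worst drawn point a†:
    ǎ = (1+α)·a_c − α·a†; renormalize the quaternion part; accept the trial
    iff it beats the population-wide worst value g_max.
    """
    k = config.N + 1
    for _ in range(_MAX_RETRIES):
        if config.include_best:
            best_i = int(np.argmin(pop.values))
            others = np.delete(np.arange(config.M), best_i)
            idx = np.concatenate([[best_i], rng.choice(others, size=k - 1, replace=False)])
        else:
            idx = rng.choice(config.M, size=k, replace=False)
        vals = pop.values[idx]
        worst_local = idx[int(np.argmax(vals))]
        vecs = np.stack([pop.points[i].to_vector() for i in idx])

        if config.weighted_centroid:
            g_min = pop.g_min
            eta = 1e-3 * (pop.g_max - g_min + 1e-12)
            w = 1.0 / (vals - g_min + eta)
            w = w / w.sum()
        else:
            w = np.full(k, 1.0 / k)
        centroid = w @ vecs

        trial_raw = (1.0 + alpha) * centroid - alpha * pop.points[worst_local].to_vector()
        try:
            trial = normalize_candidate(trial_raw)
        except DegenerateCandidateError:
            continue  # resample the N+1 subset
        try:
            v = objective(trial)
        except Exception:
            continue
        pop.eval_count += 1
        if v < pop.g_max:
            worst_global = int(np.argmax(pop.values))
            pop.points[worst_global] = trial
            pop.values[worst_global] = v
            return True
        return False
    raise DegenerateCandidateError("could not build a valid trial point")


def run_crs(
    objective: Callable[[TransformVector], float],
    domain: SearchDomain,
    config: CRSConfig | None = None,
    refine: Callable[[TransformVector], tuple[TransformVector, float]] | None = None,
) -> CRSResult:
    """Controlled random search for ``min g(a)`` over Θ.

    Stops when g_max - g_min < epsilon (absolute by default, relative to
    g_max when ``config.relative_spread``) or when ``max_evals`` objective
    evaluations have been spent (flagged non-converged).

    ``refine``, if given, is applied to the population minimizer after the
    search stops (see ``correspondence.make_refiner``): an exact local
    descent on g that sharpens the returned transform without touching the
    global phase.  The refined value is used only if it improves.
    """
    config = config or CRSConfig()
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(objective, domain, config, rng)
    trace: list[tuple[int, float, float]] = [(pop.eval_count, pop.g_min, pop.g_max)]
    spread0 = pop.spread()

    def stopped() -> bool:
        spread = pop.spread()
        if config.relative_spread:
            scale = max(abs(pop.g_max), 1e-12)
            return spread / scale < config.epsilon
        return spread < config.epsilon

    converged = stopped()
    iteration = 0
    while not converged and pop.eval_count < config.max_evals:
        alpha = update_alpha(config.alpha0, iteration, config.M, pop.spread(), spread0)
        accepted = crs_step(pop, objective, config, rng, alpha)
        iteration += 1
        if accepted:
            trace.append((pop.eval_count, pop.g_min, pop.g_max))
            logger.info(
                "accepted update: evals=%d g_min=%.6g g_max=%.6g",
                pop.eval_count, pop.g_min, pop.g_max,
            )
        converged = stopped()

    best, g_best = pop.best()
    if refine is not None:
        refined, g_refined = refine(best)
        if g_refined < g_best:
            best, g_best = refined, g_refined
            trace.append((pop.eval_count, g_best, pop.g_max))
    return CRSResult(best, g_best, converged, pop.eval_count, trace)


def write_trace(trace: list[tuple[int, float, float]], path) -> None:
    """Convergence trace as TSV (eval, g_min, g_max) for plotting."""
    with open(path, "w") as fh:
        fh.write("eval\tg_min\tg_max\n")
        for ev, lo, hi in trace:
            fh.write(f"{ev}\t{lo:.8g}\t{hi:.8g}\n")


@dataclass
class ICPResult:
    transform: TransformVector
    mapping: np.ndarray
    f: float
    n_iterations: int
    converged: bool


def run_icp(
    P: np.ndarray,
    Q: np.ndarray,
    a0: TransformVector | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ICPResult:
    """Iterative Closest Point from the initial pose ``a0``.

    Alternates the closest-point mapping with the closed-form optimal rigid
    transform for that mapping; the mean square error is non-increasing and
    the iteration stops when its decrease falls below ``tol``.  The fixed
    point reached is a local minimum that depends on ``a0``.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.size == 0 or Q.size == 0:
        raise InvalidArgumentError("point sets must be non-empty")
    a = a0 or TransformVector.identity()

    mapping = closest_point_mapping(a.apply(P), Q)
    f = mean_square_error(P, Q, mapping, a)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        a_new, f_model = optimal_transform_for_mapping(P, Q, mapping)
        mapping_new = closest_point_mapping(a_new.apply(P), Q)
        f_new = mean_square_error(P, Q, mapping_new, a_new)
        a, mapping = a_new, mapping_new
        if f - f_new < tol:
            f = min(f, f_new)
            converged = True
            break
        f = f_new
    return ICPResult(a, mapping, f, it, converged)
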