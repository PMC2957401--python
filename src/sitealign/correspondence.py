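"""Inner-problem objectives for surface alignment.

Two ways of scoring a candidate transform ``a`` against a target cloud:

* closest-point objective  g(a) = f(psi(a), a) — every transformed query
  atom is mapped to its nearest target atom; several queries may share one
  target (the mapping class Ψ, |Ψ| = m^n);
* matching distance        g(a) = f(phi(a), a) — the mapping is forced
  injective and chosen by solving a minimum-cost Asymmetric Assignment
  Problem (AAP) on the bipartite graph of query/target atoms (the class
  Φ, |Φ| = m(m-1)...(m-n+1)).

Here ``f`` is the mean square error (Å²) of the mapped pairs.  Edge costs
are squared Euclidean distances ``c_e = ||q - T_a(p)||²``.  Optionally the
graph keeps only edges between atoms of equal physico-chemical class
(ACC/DO/AD/ALI/PI), which is how chemistry enters the geometry problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import (
    InfeasibleAssignmentError,
    InfeasibleGraphError,
    InvalidArgumentError,
)
from .geometry import TransformVector, apply_transform

CompatMode = Literal["all_pairs", "same_property", "relax"]

#: factor applied to the squared cloud diameter to price fallback edges in
#: relaxed mode — large enough that a relaxed edge is only used when no
#: same-property edge can complete the assignment
RELAX_PENALTY_FACTOR = 10.0


def mean_square_error(
    P: np.ndarray, Q: np.ndarray, mapping: np.ndarray, a: TransformVector
) -> float:
    """f(psi, a) = (1/n) Σ ||psi(p) - R p - t||²  over all p in P (Å²)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    mapping = np.asarray(mapping, dtype=int)
    if mapping.shape != (P.shape[0],):
        raise InvalidArgumentError("mapping must assign every query point")
    if np.any(mapping < 0) or np.any(mapping >= Q.shape[0]):
        raise InvalidArgumentError("mapping index out of range")
    residuals = Q[mapping] - apply_transform(a, P)
    return float(np.mean(np.sum(residuals**2, axis=1)))


def closest_point_mapping(P_a: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Nearest-target index for each (already transformed) query point.

    Minimizes the mean square error over the full mapping class Ψ; the result
    need not be injective.  Ties go to the lowest target index.
    """
    P_a = np.atleast_2d(np.asarray(P_a, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P_a.size == 0 or Q.size == 0:
        raise InvalidArgumentError("point sets must be non-empty")
    # O(nm); argmin returns the first (lowest) index on exact ties
    d2 = cdist(P_a, Q, "sqeuclidean")
    return np.argmin(d2, axis=1)


@dataclass
class BipartiteCostGraph:
    """Cost graph between transformed query atoms and target atoms.

    ``cost`` is an n x m matrix of squared distances (Å²); absent edges are
    +inf.  ``n <= m`` is the caller's responsibility (swap the roles first).
    """

    cost: np.ndarray
    mode: CompatMode

    @property
    def n(self) -> int:
        return self.cost.shape[0]

    @property
    def m(self) -> int:
        return self.cost.shape[1]

    def edges(self) -> Iterable[tuple[int, int, float]]:
        ii, jj = np.nonzero(np.isfinite(self.cost))
        for i, j in zip(ii.tolist(), jj.tolist()):
            yield i, j, float(self.cost[i, j])

    def n_edges(self) -> int:
        return int(np.isfinite(self.cost).sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("p_index\tq_index\tcost\n")
            for i, j, c in self.edges():
                fh.write(f"{i}\t{j}\t{c:.6f}\n")


def _compat_mask(labels_P, labels_Q) -> np.ndarray:
    lp = np.asarray(labels_P, dtype=object)
    lq = np.asarray(labels_Q, dtype=object)
    mask = lp[:, None] == lq[None, :]
    # NONE-labeled atoms match nothing under the property filter
    mask[lp == "NONE", :] = False
    mask[:, lq == "NONE"] = False
    return mask


def _check_same_property_feasible(labels_P, labels_Q, mask: np.ndarray) -> None:
    """Raise unless an injective label-respecting assignment can exist.

    Because compatibility is label equality, the graph is a union of
    complete bipartite blocks, so Hall's condition reduces to a per-label
    count comparison: every query label class must be no larger than the
    matching target class.
    """
    lp = np.asarray(labels_P, dtype=object)
    lq = np.asarray(labels_Q, dtype=object)
    missing = np.nonzero(~mask.any(axis=1))[0]
    if missing.size:
        p = int(missing[0])
        raise InfeasibleGraphError(p, str(lp[p]))
    for label in sorted(set(lp.tolist())):
        n_p = int((lp == label).sum())
        n_q = int((lq == label).sum())
        if n_p > n_q:
            p = int(np.nonzero(lp == label)[0][0])
            raise InfeasibleGraphError(p, str(label))


def build_cost_graph(
    P_a: np.ndarray,
    Q: np.ndarray,
    labels_P=None,
    labels_Q=None,
    mode: CompatMode = "all_pairs",
) -> BipartiteCostGraph:
    """Squared-distance cost graph, optionally filtered by atom class.

    In ``same_property`` mode an edge (p, q) exists only when the two atoms
    carry the same physico-chemical label; a query atom with no compatible
    target makes the graph infeasible (error).  ``relax`` mode keeps the
    filter but adds fallback all-pairs edges at a large finite penalty
    (``RELAX_PENALTY_FACTOR`` x squared cloud diameter) so batch runs on
    real data never abort.
    """
    P_a = np.atleast_2d(np.asarray(P_a, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P_a.shape[0] > Q.shape[0]:
        raise InvalidArgumentError("query must not be larger than target (swap roles)")
    d2 = cdist(P_a, Q, "sqeuclidean")
    if mode == "all_pairs":
        return BipartiteCostGraph(d2, mode)
    if labels_P is None or labels_Q is None:
        raise InvalidArgumentError(f"mode {mode!r} requires labels for both sets")
    mask = _compat_mask(labels_P, labels_Q)
    if mode == "same_property":
        missing = np.nonzero(~mask.any(axis=1))[0]
        if missing.size:
            p = int(missing[0])
            raise InfeasibleGraphError(p, str(np.asarray(labels_P, dtype=object)[p]))
        cost = np.where(mask, d2, np.inf)
        return BipartiteCostGraph(cost, mode)
    if mode == "relax":
        all_pts = np.vstack([P_a, Q])
        span = np.linalg.norm(all_pts.max(axis=0) - all_pts.min(axis=0))
        penalty = RELAX_PENALTY_FACTOR * max(span**2, 1.0)
        cost = np.where(mask, d2, d2 + penalty)
        return BipartiteCostGraph(cost, mode)
    raise InvalidArgumentError(f"unknown compatibility mode {mode!r}")


def solve_aap(graph: BipartiteCostGraph) -> tuple[np.ndarray, float]:
    """Minimum-cost assignment: every query atom matched to exactly one target
    atom, every target atom used at most once.

    Solved by the rectangular Jonker–Volgenant algorithm; returns the target
    index for each query atom and the total selected-edge cost (Å²).
    """
    cost = graph.cost
    try:
        rows, cols = linear_sum_assignment(cost)
    except ValueError as exc:  # scipy raises on structurally infeasible matrices
        raise InfeasibleAssignmentError(str(exc)) from exc
    assignment = np.empty(graph.n, dtype=int)
    assignment[rows] = cols
    selected = cost[rows, cols]
    if not np.all(np.isfinite(selected)):
        raise InfeasibleAssignmentError("no injective assignment uses only real edges")
    return assignment, float(selected.sum())


def matching_distance(
    P: np.ndarray,
    Q: np.ndarray,
    a: TransformVector,
    labels_P=None,
    labels_Q=None,
    mode: CompatMode = "all_pairs",
) -> tuple[float, np.ndarray]:
    """The dissimilarity of T_a(P) and Q: mean square error of the optimal
    injective assignment (total AAP cost divided by n)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    graph = build_cost_graph(apply_transform(a, P), Q, labels_P, labels_Q, mode)
    assignment, total = solve_aap(graph)
    return total / graph.n, assignment


def make_refiner(
    P: np.ndarray,
    Q: np.ndarray,
    kind: "ObjectiveKind" = "matching",
    labels_P=None,
    labels_Q=None,
    mode: CompatMode = "all_pairs",
    max_iter: int = 50,
    tol: float = 1e-12,
) -> Callable[[TransformVector], tuple[TransformVector, float]]:
    """Local polish for a candidate transform by coordinate descent on g.

    Alternates the optimal inner mapping at the current transform with the
    closed-form optimal transform for that mapping (Horn).  Both half-steps
    are exact minimizations, so g is non-increasing; iteration stops at a
    fixed point.  With ``kind='closest'`` this is precisely one ICP run;
    with ``kind='matching'`` it is the assignment-based analogue.
    """
    from .geometry import optimal_transform_for_mapping

    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    g = make_objective(P, Q, kind=kind, labels_P=labels_P, labels_Q=labels_Q, mode=mode)

    def mapping_at(a: TransformVector) -> np.ndarray:
        P_a = apply_transform(a, P)
        if kind == "closest":
            graph = build_cost_graph(P_a, Q, labels_P, labels_Q, mode)
            return np.argmin(graph.cost, axis=1)
        graph = build_cost_graph(P_a, Q, labels_P, labels_Q, mode)
        assignment, _ = solve_aap(graph)
        return assignment

    def refine(a: TransformVector) -> tuple[TransformVector, float]:
        f = g(a)
        for _ in range(max_iter):
            psi = mapping_at(a)
            a_new, _ = optimal_transform_for_mapping(P, Q, psi)
            f_new = g(a_new)
            if f_new >= f - tol:
                if f_new < f:
                    a, f = a_new, f_new
                break
            a, f = a_new, f_new
        return a, f

    return refine


ObjectiveKind = Literal["closest", "matching"]


def objective(
    P: np.ndarray,
    Q: np.ndarray,
    a: TransformVector,
    kind: ObjectiveKind = "matching",
    labels_P=None,
    labels_Q=None,
    mode: CompatMode = "all_pairs",
) -> float:
    """Evaluate g(a) for the selected inner problem.

    ``matching`` >= ``closest`` for the same inputs: injectivity can only
    raise the optimum over the mapping class.
    """
    fn = make_objective(P, Q, kind=kind, labels_P=labels_P, labels_Q=labels_Q, mode=mode)
    return fn(a)


def make_objective(
    P: np.ndarray,
    Q: np.ndarray,
    kind: ObjectiveKind = "matching",
    labels_P=None,
    labels_Q=None,
    mode: CompatMode = "all_pairs",
) -> Callable[[TransformVector], float]:
    """Bind (P, Q, labels, mode) into a fast ``g(a)`` for the optimizer.

    The compatibility mask and relax penalty are precomputed once; each call
    costs one n x m distance matrix plus (for ``matching``) one assignment
    solve.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.size == 0 or Q.size == 0:
        raise InvalidArgumentError("point sets must be non-empty")
    if kind not in ("closest", "matching"):
        raise InvalidArgumentError(f"unknown objective kind {kind!r}")
    if P.shape[0] > Q.shape[0] and kind == "matching":
        raise InvalidArgumentError("query must not be larger than target (swap roles)")
    n = P.shape[0]

    mask = None
    penalty = None
    if mode in ("same_property", "relax"):
        if labels_P is None or labels_Q is None:
            raise InvalidArgumentError(f"mode {mode!r} requires labels for both sets")
        mask = _compat_mask(labels_P, labels_Q)
        if mode == "same_property":
            if kind == "matching":
                # injectivity makes label counts binding, not just per-atom edges
                _check_same_property_feasible(labels_P, labels_Q, mask)
            else:
                missing = np.nonzero(~mask.any(axis=1))[0]
                if missing.size:
                    p = int(missing[0])
                    raise InfeasibleGraphError(
                        p, str(np.asarray(labels_P, dtype=object)[p])
                    )
        if mode == "relax":
            all_pts = np.vstack([P, Q])
            span = np.linalg.norm(all_pts.max(axis=0) - all_pts.min(axis=0))
            penalty = RELAX_PENALTY_FACTOR * max(span**2, 1.0)
    elif mode != "all_pairs":
        raise InvalidArgumentError(f"unknown compatibility mode {mode!r}")

    rot_cache_P = np.ascontiguousarray(P)

    def g(a: TransformVector) -> float:
        P_a = rot_cache_P @ a.rotation().T + a.translation
        d2 = cdist(P_a, Q, "sqeuclidean")
        if mask is not None:
            if mode == "relax":
                d2 = np.where(mask, d2, d2 + penalty)
            else:
                d2 = np.where(mask, d2, np.inf)
        if kind == "closest":
            return float(np.min(d2, axis=1).mean())
        rows, cols = linear_sum_assignment(d2)
        selected = d2[rows, cols]
        if not np.all(np.isfinite(selected)):
            raise InfeasibleAssignmentError(
                "no injective assignment uses only real edges"
            )
        return float(selected.sum()) / n

    return g
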