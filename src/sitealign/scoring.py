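"""Post-alignment scores, the full alignment pipeline, and batch evaluation.

Given an optimized transform and assignment, an alignment is summarized by:

* ``n_aligned`` — assigned pairs within a post-superposition distance
  cutoff (2.0 Å by default);
* ``RMSD`` (Å) — root-mean-square deviation over exactly those pairs;
* ``SAS`` = RMSD x 100 / n_aligned — a single match-quality number that
  rewards many aligned atoms at low RMSD (lower is better);
* ``similarity`` = 2·n_aligned / (n + m) ∈ [0, 1] — the size-normalized
  score used for all-vs-all matrices.

The aligned-atom cutoff is the one free choice here: a total assignment
pairs every query atom, so "aligned" pairs must be selected by a distance
threshold.  See docs/methods.md for the consequences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import correspondence, geometry, optimizer
from .errors import InvalidArgumentError, UndefinedScoreError
from .structure_io import SurfacePatch

logger = logging.getLogger(__name__)

#: post-superposition distance (Å) within which an assigned pair counts as aligned
DEFAULT_ALIGNED_CUTOFF = 2.0


def aligned_pairs(
    assignment: np.ndarray,
    P_a: np.ndarray,
    Q: np.ndarray,
    cutoff: float = DEFAULT_ALIGNED_CUTOFF,
) -> list[tuple[int, int, float]]:
    """Assigned pairs whose post-superposition distance is <= cutoff.

    Returns (p index, q index, distance Å) triples in query order.
    """
    P_a = np.atleast_2d(np.asarray(P_a, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    assignment = np.asarray(assignment, dtype=int)
    dists = np.linalg.norm(Q[assignment] - P_a, axis=1)
    return [
        (i, int(assignment[i]), float(dists[i]))
        for i in range(len(assignment))
        if dists[i] <= cutoff
    ]


def rmsd(distances: Sequence[float]) -> float:
    """Root-mean-square of pair distances (Å)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise UndefinedScoreError("RMSD is undefined for zero pairs")
    return float(np.sqrt(np.mean(d**2)))


def sas(rmsd_value: float, n_aligned: int) -> float:
    """Size-adjusted score: RMSD x 100 / number of aligned atoms."""
    if n_aligned < 1:
        raise UndefinedScoreError("SAS is undefined for zero aligned atoms")
    return rmsd_value * 100.0 / n_aligned


def similarity(n_aligned: int, n: int, m: int) -> float:
    """Normalized similarity 2·aligned/(n+m); 1 for a perfect self-match."""
    if n < 1 or m < 1:
        raise InvalidArgumentError("patch sizes must be positive")
    if not (0 <= n_aligned <= min(n, m)):
        raise InvalidArgumentError("aligned count must lie in [0, min(n, m)]")
    return 2.0 * n_aligned / (n + m)


# ---------------------------------------------------------------------------
# published benchmark statistics (ATP-binding-site comparisons against the
# catalytic subunit of cAMP-dependent protein kinase, PDB 1ATP chain E):
# per-pair aligned-atom counts and RMSDs as reported for the continuous-
# optimization aligner (co_*) and for the MolLoc web server (molloc_*).
ATP_BENCHMARK: list[dict] = [
    {"pair": "1atpE-1hck", "co_aligned": 62, "co_rmsd": 1.2, "molloc_aligned": 45, "molloc_rmsd": 1.3},
    {"pair": "1atpE-1phk", "co_aligned": 57, "co_rmsd": 0.91, "molloc_aligned": 63, "molloc_rmsd": 0.9},
    {"pair": "1atpE-1csn", "co_aligned": 50, "co_rmsd": 1.18, "molloc_aligned": 55, "molloc_rmsd": 0.9},
    {"pair": "1atpE-1nsf", "co_aligned": 34, "co_rmsd": 2.11, "molloc_aligned": 11, "molloc_rmsd": 1.4},
    {"pair": "1atpE-1j7k", "co_aligned": 25, "co_rmsd": 1.81, "molloc_aligned": 25, "molloc_rmsd": 1.6},
    {"pair": "1atpE-1e8xA", "co_aligned": 24, "co_rmsd": 1.74, "molloc_aligned": 20, "molloc_rmsd": 1.7},
    {"pair": "1atpE-1f9aC", "co_aligned": 21, "co_rmsd": 2.17, "molloc_aligned": 18, "molloc_rmsd": 1.6},
    {"pair": "1atpE-1kay", "co_aligned": 20, "co_rmsd": 1.9, "molloc_aligned": 8, "molloc_rmsd": 1.7},
    {"pair": "1atpE-1yag", "co_aligned": 20, "co_rmsd": 1.92, "molloc_aligned": 17, "molloc_rmsd": 1.6},
    {"pair": "1atpE-1a82", "co_aligned": 19, "co_rmsd": 2.02, "molloc_aligned": 13, "molloc_rmsd": 1.9},
    {"pair": "1atpE-1jjv", "co_aligned": 18, "co_rmsd": 1.76, "molloc_aligned": 10, "molloc_rmsd": 1.8},
    {"pair": "1atpE-1gn8A", "co_aligned": 17, "co_rmsd": 2.37, "molloc_aligned": 14, "molloc_rmsd": 1.6},
    {"pair": "1atpE-1b8aA", "co_aligned": 16, "co_rmsd": 2.05, "molloc_aligned": 10, "molloc_rmsd": 2.0},
    {"pair": "1atpE-1mjhA", "co_aligned": 16, "co_rmsd": 2.28, "molloc_aligned": 14, "molloc_rmsd": 1.9},
    {"pair": "1atpE-1e2q", "co_aligned": 15, "co_rmsd": 1.39, "molloc_aligned": 5, "molloc_rmsd": 1.8},
    {"pair": "1atpE-1kp2A", "co_aligned": 13, "co_rmsd": 1.51, "molloc_aligned": 15, "molloc_rmsd": 1.9},
    {"pair": "1atpE-1ayl", "co_aligned": 12, "co_rmsd": 1.21, "molloc_aligned": 16, "molloc_rmsd": 2.0},
    {"pair": "1atpE-1g5t", "co_aligned": 7, "co_rmsd": 2.26, "molloc_aligned": 8, "molloc_rmsd": 1.6},
]


def benchmark_mean_sas(method: str = "co") -> float:
    """Mean over the benchmark table of the unrounded per-pair SAS for the
    selected method ('co' or 'molloc')."""
    if method not in ("co", "molloc"):
        raise InvalidArgumentError("method must be 'co' or 'molloc'")
    values = [
        sas(row[f"{method}_rmsd"], row[f"{method}_aligned"]) for row in ATP_BENCHMARK
    ]
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# full alignment pipeline


@dataclass
class AlignmentReport:
    """Everything a single pairwise alignment produced."""

    transform: geometry.TransformVector
    pairs: list[tuple[int, int, float]]  # (query atom, target atom, distance Å)
    n_aligned: int
    rmsd: float | None
    sas: float | None
    similarity: float
    objective_value: float
    n_query: int
    n_target: int
    converged: bool
    swapped: bool
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "transform": {
                "quaternion": self.transform.quaternion.tolist(),
                "translation": self.transform.translation.tolist(),
            },
            "pairs": [[int(p), int(q), round(d, 4)] for p, q, d in self.pairs],
            "n_aligned": self.n_aligned,
            "rmsd": None if self.rmsd is None else round(self.rmsd, 4),
            "sas": None if self.sas is None else round(self.sas, 2),
            "similarity": round(self.similarity, 4),
            "objective_value": self.objective_value,
            "n_query": self.n_query,
            "n_target": self.n_target,
            "converged": self.converged,
            "swapped": self.swapped,
            "config": self.config,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_pairs_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("query_atom\ttarget_atom\tdistance\n")
            for p, q, d in self.pairs:
                fh.write(f"{p}\t{q}\t{d:.4f}\n")


def align_patches(
    query: SurfacePatch,
    target: SurfacePatch,
    objective_kind: str = "matching",
    mode: str = "same_property",
    aligned_cutoff: float = DEFAULT_ALIGNED_CUTOFF,
    crs_config: optimizer.CRSConfig | None = None,
    domain: geometry.SearchDomain | None = None,
) -> AlignmentReport:
    """Optimize the superposition of two patches and score the result.

    The smaller patch always plays the query role internally (the matching
    distance requires n <= m); if the caller's patches are swapped for this,
    the reported transform is inverted and the pair table transposed so the
    report is always expressed as query -> target in the caller's sense.
    """
    swapped = len(query) > len(target)
    P, Q = (target, query) if swapped else (query, target)

    crs_config = crs_config or optimizer.CRSConfig()
    domain = domain or geometry.SearchDomain.around(P.coords, Q.coords)
    g = correspondence.make_objective(
        P.coords, Q.coords, kind=objective_kind,
        labels_P=P.labels, labels_Q=Q.labels, mode=mode,
    )
    refine = correspondence.make_refiner(
        P.coords, Q.coords, kind=objective_kind,
        labels_P=P.labels, labels_Q=Q.labels, mode=mode,
    )
    result = optimizer.run_crs(g, domain, crs_config, refine=refine)

    if objective_kind == "matching":
        f_value, assignment = correspondence.matching_distance(
            P.coords, Q.coords, result.best,
            labels_P=P.labels, labels_Q=Q.labels, mode=mode,
        )
    else:
        P_best = result.best.apply(P.coords)
        assignment = correspondence.closest_point_mapping(P_best, Q.coords)
        f_value = correspondence.mean_square_error(P.coords, Q.coords, assignment, result.best)

    P_best = result.best.apply(P.coords)
    pairs = aligned_pairs(assignment, P_best, Q.coords, cutoff=aligned_cutoff)
    n_aligned = len(pairs)
    distances = [d for _, _, d in pairs]
    rmsd_value = rmsd(distances) if n_aligned else None
    sas_value = sas(rmsd_value, n_aligned) if n_aligned else None
    sim = similarity(n_aligned, len(query), len(target))

    transform = result.best
    if swapped:
        transform = transform.inverse()
        pairs = [(q, p, d) for p, q, d in pairs]

    return AlignmentReport(
        transform=transform,
        pairs=pairs,
        n_aligned=n_aligned,
        rmsd=rmsd_value,
        sas=sas_value,
        similarity=sim,
        objective_value=result.g_best,
        n_query=len(query),
        n_target=len(target),
        converged=result.converged,
        swapped=swapped,
        config={
            "objective": objective_kind,
            "mode": mode,
            "aligned_cutoff": aligned_cutoff,
            "M": crs_config.M,
            "epsilon": crs_config.epsilon,
            "alpha0": crs_config.alpha0,
            "max_evals": crs_config.max_evals,
            "seed": crs_config.seed,
        },
    )


def all_vs_all(
    patches: Sequence[SurfacePatch],
    names: Sequence[str] | None = None,
    **align_kwargs,
) -> tuple[np.ndarray, dict[tuple[int, int], AlignmentReport]]:
    """Similarity matrix over every unordered pair of patches.

    Each pair is aligned once (the smaller patch as query) and the
    similarity entered symmetrically; the diagonal holds self-similarities.
    A failed pair is logged and left as NaN.
    """
    k = len(patches)
    if k < 2:
        raise InvalidArgumentError("need at least two patches")
    matrix = np.full((k, k), np.nan)
    reports: dict[tuple[int, int], AlignmentReport] = {}
    for i in range(k):
        for j in range(i, k):
            try:
                rep = align_patches(patches[i], patches[j], **align_kwargs)
            except Exception as exc:
                label = names[i] if names else i
                label2 = names[j] if names else j
                logger.warning("alignment %s vs %s failed: %s", label, label2, exc)
                continue
            matrix[i, j] = matrix[j, i] = rep.similarity
            reports[(i, j)] = rep
    return matrix, reports


def write_matrix_tsv(matrix: np.ndarray, names: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(names) + "\n")
        for i, name in enumerate(names):
            row = "\t".join(
                "NA" if np.isnan(v) else f"{v:.4f}" for v in matrix[i]
            )
            fh.write(f"{name}\t{row}\n")


# ---------------------------------------------------------------------------
# retrieval evaluation


def roc_curve_points(
    scores: Sequence[float], is_positive: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR) and AUC for one ranked retrieval list.

    Higher scores rank earlier (more aligned atoms = better).  Requires both
    classes to be present.
    """
    y = np.asarray(is_positive, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise UndefinedScoreError("ROC needs both positive and negative pairs")
    from sklearn.metrics import roc_curve as _roc, roc_auc_score

    fpr, tpr, _ = _roc(y, s)
    return fpr, tpr, float(roc_auc_score(y, s))


def roc_retrieval(
    pair_scores: dict[tuple[str, str], float], groups: dict[str, str]
) -> dict:
    """Per-query ROC curves and per-group average curves.

    ``pair_scores`` maps unordered (query, other) name pairs to a ranking
    score (typically the aligned-atom count, similarity as tie-breaker);
    ``groups`` maps each name to its ligand group.  For each query, the
    remaining items are ranked and an item counts as a true positive when it
    shares the query's group.  Group curves are averages of the member
    queries' TPR on a common FPR grid.
    """
    names = sorted(groups)
    per_query: dict[str, dict] = {}
    grid = np.linspace(0.0, 1.0, 101)
    group_curves: dict[str, list[np.ndarray]] = {}
    for query in names:
        scores, positives = [], []
        for other in names:
            if other == query:
                continue
            key = (query, other) if (query, other) in pair_scores else (other, query)
            if key not in pair_scores:
                continue
            scores.append(pair_scores[key])
            positives.append(groups[other] == groups[query])
        if not scores or all(positives) or not any(positives):
            logger.warning("query %s skipped: degenerate class composition", query)
            continue
        fpr, tpr, auc = roc_curve_points(scores, positives)
        per_query[query] = {"fpr": fpr, "tpr": tpr, "auc": auc}
        interp = np.interp(grid, fpr, tpr)
        group_curves.setdefault(groups[query], []).append(interp)
    per_group = {
        grp: {"fpr": grid, "tpr": np.mean(curves, axis=0),
              "auc": float(np.trapezoid(np.mean(curves, axis=0), grid))}
        for grp, curves in group_curves.items()
    }
    return {"per_query": per_query, "per_group": per_group}
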