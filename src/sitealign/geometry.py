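"""Rigid-body transforms in 3D parameterized by unit quaternions.

A transform is the 7-vector ``a = (a_r, a_t)``: a unit quaternion
``a_r = (a0, a1, a2, a3)`` encoding the rotation and a translation
``a_t`` in Å.  Applying it to a point ``x`` gives ``R(a_r) x + a_t``.

Because ``q`` and ``-q`` encode the same rotation (double cover of SO(3)),
quaternions are kept in a canonical half-space: ``a0 >= 0``, ties resolved
by the first nonzero component.  This makes transforms directly comparable
across an optimizer population.

Also provided: the closed-form optimal rigid transform for a fixed
point-to-point mapping (Horn's absolute-orientation quaternion method),
random sampling of transforms over a search domain, and the quaternion
renormalization used by the optimizer's reflection step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCandidateError, InvalidArgumentError

#: tolerance for accepting a quaternion as "unit" on input
UNIT_TOL = 1e-6


def _canonical(q: np.ndarray) -> np.ndarray:
    """Flip sign so the first nonzero component is positive."""
    for c in q:
        if c > 0.0:
            return q
        if c < 0.0:
            return -q
    return q


@dataclass(frozen=True)
class TransformVector:
    """Unit quaternion + translation; the optimizer's decision variable."""

    quaternion: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(t))):
            raise InvalidArgumentError("transform components must be finite")
        norm = float(np.linalg.norm(q))
        if abs(norm - 1.0) > UNIT_TOL:
            raise InvalidArgumentError(
                f"quaternion norm {norm:.6g} differs from 1 beyond tolerance"
            )
        q = _canonical(q / norm)
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "translation", t)
        self.quaternion.setflags(write=False)
        self.translation.setflags(write=False)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "TransformVector":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_vector(cls, vec7: np.ndarray) -> "TransformVector":
        vec7 = np.asarray(vec7, dtype=float).reshape(7)
        return cls(vec7[:4], vec7[4:])

    # -- views ------------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.quaternion, self.translation])

    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.quaternion)

    def matrix4(self) -> np.ndarray:
        """4x4 homogeneous matrix, for molecular viewers."""
        m = np.eye(4)
        m[:3, :3] = self.rotation()
        m[:3, 3] = self.translation
        return m

    # -- algebra ----------------------------------------------------------
    def compose(self, other: "TransformVector") -> "TransformVector":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        q = _quat_multiply(self.quaternion, other.quaternion)
        t = self.rotation() @ other.translation + self.translation
        return TransformVector(q, t)

    def inverse(self) -> "TransformVector":
        q_inv = self.quaternion * np.array([1.0, -1.0, -1.0, -1.0])
        r_inv = rotation_matrix(q_inv)
        return TransformVector(q_inv, -(r_inv @ self.translation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "quaternion": self.quaternion.tolist(),
                "translation": self.translation.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransformVector":
        obj = json.loads(text)
        return cls(np.asarray(obj["quaternion"]), np.asarray(obj["translation"]))


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a0, a1, a2, a3 = a
    b0, b1, b2, b3 = b
    return np.array(
        [
            a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
        ]
    )


def rotation_matrix(a_r: np.ndarray) -> np.ndarray:
    """3x3 proper rotation matrix of a unit quaternion (Horn convention).

    Raises if the quaternion is not unit within tolerance.
    """
    q = np.asarray(a_r, dtype=float).reshape(4)
    norm = float(np.linalg.norm(q))
    if abs(norm - 1.0) > UNIT_TOL:
        raise InvalidArgumentError(
            f"rotation_matrix requires a unit quaternion, got norm {norm:.6g}"
        )
    a0, a1, a2, a3 = q / norm
    return np.array(
        [
            [
                a0 * a0 + a1 * a1 - a2 * a2 - a3 * a3,
                2.0 * (a1 * a2 - a0 * a3),
                2.0 * (a1 * a3 + a0 * a2),
            ],
            [
                2.0 * (a1 * a2 + a0 * a3),
                a0 * a0 + a2 * a2 - a1 * a1 - a3 * a3,
                2.0 * (a2 * a3 - a0 * a1),
            ],
            [
                2.0 * (a1 * a3 - a0 * a2),
                2.0 * (a2 * a3 + a0 * a1),
                a0 * a0 + a3 * a3 - a1 * a1 - a2 * a2,
            ],
        ]
    )


def apply_transform(a: TransformVector, points: np.ndarray) -> np.ndarray:
    """Apply ``y = R(a_r) x + a_t`` to every row of ``points`` (n x 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise InvalidArgumentError("cannot transform an empty point set")
    if pts.shape[1] != 3 or not np.all(np.isfinite(pts)):
        raise InvalidArgumentError("points must be a finite n x 3 array")
    return pts @ a.rotation().T + a.translation


def optimal_transform_for_mapping(
    P: np.ndarray, Q: np.ndarray, psi: np.ndarray
) -> tuple[TransformVector, float]:
    """Closed-form rigid transform minimizing the mean square error for fixed psi.

    Horn's quaternion method: the optimal rotation is the eigenvector of the
    4x4 cross-covariance matrix with the largest eigenvalue; the translation
    aligns the centroids.  Returns the transform and the attained mean square
    error (Å²).  If all mapped points are coincident (rank-0 covariance) the
    rotation is left as the identity and only the centroids are aligned.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    psi = np.asarray(psi, dtype=int)
    if P.shape[0] < 1:
        raise InvalidArgumentError("need at least one point")
    if psi.shape != (P.shape[0],):
        raise InvalidArgumentError("mapping must give one target index per query point")
    if np.any(psi < 0) or np.any(psi >= Q.shape[0]):
        raise InvalidArgumentError("mapping index out of range")

    targets = Q[psi]
    p_bar = P.mean(axis=0)
    q_bar = targets.mean(axis=0)
    Pc = P - p_bar
    Qc = targets - q_bar
    S = Pc.T @ Qc  # 3x3 cross-covariance, S_ab = sum_i p_ia q_ib

    if np.linalg.norm(S) < 1e-12:
        # degenerate: all mapped points coincident -> centroid translation
        a = TransformVector(np.array([1.0, 0.0, 0.0, 0.0]), q_bar - p_bar)
    else:
        Sxx, Sxy, Sxz = S[0]
        Syx, Syy, Syz = S[1]
        Szx, Szy, Szz = S[2]
        N = np.array(
            [
                [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
                [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
                [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
                [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
            ]
        )
        w, V = np.linalg.eigh(N)
        q = V[:, np.argmax(w)]
        q = _canonical(q / np.linalg.norm(q))
        R = rotation_matrix(q)
        a = TransformVector(q, q_bar - R @ p_bar)

    residuals = targets - apply_transform(a, P)
    f = float(np.mean(np.sum(residuals**2, axis=1)))
    return a, f


@dataclass(frozen=True)
class SearchDomain:
    """Feasible domain Θ: the unit 3-sphere (implicit) times a translation box."""

    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        low = np.asarray(self.low, dtype=float).reshape(3)
        high = np.asarray(self.high, dtype=float).reshape(3)
        if not (np.all(np.isfinite(low)) and np.all(np.isfinite(high))):
            raise InvalidArgumentError("translation bounds must be finite")
        if not np.all(low < high):
            raise InvalidArgumentError("translation bounds require low < high per axis")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)
        self.low.setflags(write=False)
        self.high.setflags(write=False)

    @classmethod
    def around(cls, P: np.ndarray, Q: np.ndarray) -> "SearchDomain":
        """Default box: centered on centroid(Q) - centroid(P), wide enough per
        axis to contain any translation superposing the two clouds."""
        P = np.atleast_2d(np.asarray(P, dtype=float))
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        center = Q.mean(axis=0) - P.mean(axis=0)
        half = _diameter(P) / 2.0 + _diameter(Q) / 2.0
        half = max(half, 1.0)  # keep the box non-degenerate for single points
        return cls(center - half, center + half)


def _diameter(X: np.ndarray) -> float:
    """Diameter of a point cloud (max pairwise distance, via bounding box upper
    bound for speed is not enough here; n is small so do it exactly)."""
    if X.shape[0] == 1:
        return 0.0
    from scipy.spatial.distance import pdist

    return float(pdist(X).max())


def random_transform(domain: SearchDomain, rng: np.random.Generator) -> TransformVector:
    """Sample a transform: quaternion uniform on S^3, translation uniform in box."""
    while True:
        raw = rng.standard_normal(4)
        norm = np.linalg.norm(raw)
        if norm > 1e-12:
            break
    q = _canonical(raw / norm)
    t = rng.uniform(domain.low, domain.high)
    return TransformVector(q, t)


def normalize_candidate(a_raw: np.ndarray) -> TransformVector:
    """Renormalize a trial 7-vector: divide the quaternion part by its norm ξ,
    leave the translation untouched (the reflection step's W matrix)."""
    vec = np.asarray(a_raw, dtype=float).reshape(7)
    xi = float(np.linalg.norm(vec[:4]))
    if xi < 1e-12:
        raise DegenerateCandidateError(
            "quaternion part of candidate has near-zero norm; resample"
        )
    return TransformVector(vec[:4] / xi, vec[4:])


def transform_deviation(a: TransformVector, b: TransformVector) -> float:
    """Scalar discrepancy between two transforms.

    Composes ``a`` with ``b``'s inverse and measures the departure from the
    identity: max of the quaternion distance (double cover resolved) and the
    residual translation norm.  Zero iff the transforms are identical.
    """
    delta = a.compose(b.inverse())
    q = delta.quaternion
    e = np.array([1.0, 0.0, 0.0, 0.0])
    dq = min(np.linalg.norm(q - e), np.linalg.norm(q + e))
    return float(max(dq, np.linalg.norm(delta.translation)))
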