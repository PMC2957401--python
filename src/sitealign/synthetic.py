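"""Synthetic alignment instances with known ground truth.

Generates pairs of labeled point clouds related by a known rigid transform,
with optional isotropic Gaussian coordinate noise and decoy atoms, plus
mock PDB files whose 4.0 Å ligand shell recovers exactly the planted patch.
These instances stand in for real binding-site pairs in tests and let every
stage of the pipeline — extraction, typing, optimization, scoring — be
exercised end to end with a checkable answer.

Decoy atoms are sampled inside the bounding box of the true target atoms
but kept at least ``2*sigma + 1`` Å away from every true atom, so at zero
noise the planted assignment is the unique optimum of the matching
distance at the ground-truth transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .geometry import SearchDomain, TransformVector, random_transform
from .structure_io import SurfacePatch

#: edge length (Å) of the cube the query cloud is sampled in
BOX_SIZE = 20.0

#: how each label is encoded as a (residue, atom, element) triple in mock
#: PDB files; chosen so re-typing the file reproduces the label exactly
LABEL_ATOMS = {
    "ACC": ("ASP", "OD1", "O"),
    "DO": ("LYS", "NZ", "N"),
    "AD": ("SER", "OG", "O"),
    "ALI": ("ALA", "CB", "C"),
    "PI": ("PHE", "CG", "C"),
    "NONE": ("UNK", "X1", "X"),
}

_CLASSES = ("ACC", "DO", "AD", "ALI", "PI")


@dataclass(frozen=True)
class SyntheticInstance:
    P: SurfacePatch
    Q: SurfacePatch
    ground_truth: TransformVector
    sigma: float
    n_decoys: int
    correspondence: np.ndarray  # index into Q of each P atom's true partner
    seed: int


def _patch_from(coords, labels, source) -> SurfacePatch:
    n = coords.shape[0]
    res_names = np.array([LABEL_ATOMS[l][0] for l in labels], dtype=object)
    atom_names = np.array([LABEL_ATOMS[l][1] for l in labels], dtype=object)
    elements = np.array([LABEL_ATOMS[l][2] for l in labels], dtype=object)
    return SurfacePatch(
        coords=coords,
        chain_ids=np.full(n, "A", dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=res_names,
        atom_names=atom_names,
        elements=elements,
        labels=np.asarray(labels, dtype=object),
        source=source,
    )


def make_instance(
    n: int = 20,
    decoys: int = 0,
    sigma: float = 0.0,
    transform: TransformVector | None = None,
    label_scheme: str = "compatible",
    seed: int = 0,
) -> SyntheticInstance:
    """Plant a query cloud P, its transformed copy inside Q, and decoys.

    P is uniform in a 20 Å cube centered at the origin.  Q holds the true
    correspondents ``T(P) + N(0, sigma² I)`` plus ``decoys`` distractor
    atoms, all shuffled.  ``label_scheme``:

    * ``compatible`` — labels drawn uniformly from the five classes and
      copied to the true correspondents (true pairs always pass the
      same-property filter); decoys get independent labels;
    * ``random`` — every atom labeled independently.
    """
    if n < 3:
        raise InvalidArgumentError("need at least 3 query atoms")
    if sigma < 0 or decoys < 0:
        raise InvalidArgumentError("sigma and decoys must be non-negative")
    if label_scheme not in ("compatible", "random"):
        raise InvalidArgumentError(f"unknown label scheme {label_scheme!r}")
    rng = np.random.default_rng(seed)

    half = BOX_SIZE / 2.0
    P_coords = rng.uniform(-half, half, size=(n, 3))
    if transform is None:
        transform = random_transform(
            SearchDomain(-np.full(3, half), np.full(3, half)), rng
        )
    true_Q = transform.apply(P_coords) + rng.normal(0.0, sigma, size=(n, 3))

    margin = 2.0 * sigma + 1.0
    lo, hi = true_Q.min(axis=0) - margin, true_Q.max(axis=0) + margin
    decoy_coords = []
    attempts = 0
    while len(decoy_coords) < decoys:
        cand = rng.uniform(lo, hi, size=3)
        if np.min(np.linalg.norm(true_Q - cand, axis=1)) >= margin:
            decoy_coords.append(cand)
        attempts += 1
        if attempts > 10_000 * max(decoys, 1):
            raise InvalidArgumentError(
                "could not place decoys with the required margin; too crowded"
            )
    Q_coords = np.vstack([true_Q] + decoy_coords) if decoys else true_Q

    P_labels = rng.choice(_CLASSES, size=n)
    if label_scheme == "compatible":
        true_labels = P_labels.copy()
    else:
        true_labels = rng.choice(_CLASSES, size=n)
    decoy_labels = rng.choice(_CLASSES, size=decoys)
    Q_labels = np.concatenate([true_labels, decoy_labels])

    perm = rng.permutation(n + decoys)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(n + decoys)
    Q_coords = Q_coords[perm]
    Q_labels = Q_labels[perm]
    correspondence = inv[:n]  # Q index of P atom i's true partner

    P = _patch_from(P_coords, P_labels, f"synthetic seed={seed} role=P")
    Q = _patch_from(Q_coords, Q_labels, f"synthetic seed={seed} role=Q")
    return SyntheticInstance(P, Q, transform, sigma, decoys, correspondence, seed)


def make_symmetric_decoy_instance(seed: int = 0) -> SyntheticInstance:
    """A two-cluster cloud whose 180°-rotated pose is a deep local minimum.

    Two clusters of distinct internal shape sit 20 Å apart; the target is an
    exact clone (identity ground truth).  Starting ICP from the 180°-rotated
    pose locks each cluster onto the other and converges to a nonzero local
    minimum, while a global search finds the exact superposition.
    """
    rng = np.random.default_rng(seed)
    cluster_a = rng.uniform(-2.5, 2.5, size=(10, 3))
    cluster_b = rng.uniform(-2.0, 2.0, size=(10, 3)) * np.array([1.0, 0.4, 1.6])
    cluster_b = cluster_b + np.array([20.0, 0.0, 0.0])
    coords = np.vstack([cluster_a, cluster_b])
    labels = rng.choice(_CLASSES, size=20)
    P = _patch_from(coords, labels, f"synthetic symmetric-decoy seed={seed} role=P")
    Q = _patch_from(coords.copy(), labels.copy(), f"synthetic symmetric-decoy seed={seed} role=Q")
    return SyntheticInstance(
        P, Q, TransformVector.identity(), 0.0, 0, np.arange(20), seed
    )


def adversarial_start() -> TransformVector:
    """180° rotation about the z axis through the symmetric-decoy midpoint:
    maps each cluster onto the other's location."""
    # R = diag(-1,-1,1); t chosen so x -> (20,0,0) - x in the xy-plane
    return TransformVector(np.array([0.0, 0.0, 0.0, 1.0]), np.array([20.0, 0.0, 0.0]))


def write_mock_pdb(instance: SyntheticInstance, path, which: str = "P") -> None:
    """Write one patch of the instance as a PDB file with a fake ligand.

    Patch atoms become ATOM records (one residue per atom, names encoding
    the labels); the ligand is a HETATM copy of the patch offset by ~1 Å per
    atom, so extraction with the default 4.0 Å shell recovers exactly the
    patch while a very small cutoff recovers only part of it.
    """
    patch = instance.P if which == "P" else instance.Q
    rng = np.random.default_rng(instance.seed + 7919)
    lines = []
    serial = 1
    for i in range(len(patch)):
        x, y, z = patch.coords[i]
        lines.append(
            _pdb_line("ATOM", serial, str(patch.atom_names[i]), str(patch.res_names[i]),
                      "A", int(patch.res_ids[i]), x, y, z, str(patch.elements[i]))
        )
        serial += 1
    for i in range(len(patch)):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        offset = 0.3 if i == 0 else 1.0
        x, y, z = patch.coords[i] + offset * direction
        lines.append(
            _pdb_line("HETATM", serial, f"C{i % 99 + 1}", "LIG", "L", 900 + i // 99,
                      x, y, z, "C")
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_line(record, serial, atom_name, res_name, chain, res_id, x, y, z, element):
    name = atom_name if len(atom_name) >= 4 else f" {atom_name}"
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{res_name:<3} {chain}"
        f"{res_id:>4}{'':1}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )
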