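"""PDB ingestion, binding-site extraction and physico-chemical atom typing.

A binding site ("surface patch") is the set of protein heavy atoms within a
distance cutoff — 4.0 Å by default — of any atom of a bound ligand.  Each
atom carries one of six physico-chemical labels: hydrogen-bond acceptor
(ACC), donor (DO), acceptor/donor (AD), aliphatic carbon (ALI), aromatic
ring atom (PI), or NONE for atoms outside the classification.  Labels come
from a shipped per-(residue, atom) rule table with element-based fallbacks,
so the table can be edited without touching code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import InvalidArgumentError, LigandNotFoundError, ParseError

logger = logging.getLogger(__name__)

LABELS = ("ACC", "DO", "AD", "ALI", "PI", "NONE")

#: extraction shell radius in Å (distance from any ligand atom, inclusive)
DEFAULT_CUTOFF = 4.0

_ELEMENT_FALLBACK = {"N": "DO", "O": "ACC", "C": "ALI", "S": "ALI"}


@dataclass(frozen=True)
class SurfacePatch:
    """A labeled finite point set: the atoms of one binding site."""

    coords: np.ndarray  # n x 3, Å
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    labels: np.ndarray  # each in LABELS
    source: str = ""

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.shape[0] < 1 or coords.shape[1] != 3:
            raise InvalidArgumentError("a patch needs at least one 3D atom")
        if not np.all(np.isfinite(coords)):
            raise InvalidArgumentError("patch coordinates must be finite")
        n = coords.shape[0]
        object.__setattr__(self, "coords", coords)
        for name in ("chain_ids", "res_ids", "res_names", "atom_names", "elements", "labels"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise InvalidArgumentError(f"{name} must have one entry per atom")
            object.__setattr__(self, name, arr)
        bad = set(self.labels.tolist()) - set(LABELS)
        if bad:
            raise InvalidArgumentError(f"unknown labels {sorted(bad)}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    def subset(self, idx) -> "SurfacePatch":
        idx = np.asarray(idx)
        return SurfacePatch(
            self.coords[idx], self.chain_ids[idx], self.res_ids[idx],
            self.res_names[idx], self.atom_names[idx], self.elements[idx],
            self.labels[idx], self.source,
        )

    def atom_keys(self) -> list[tuple]:
        """(chain, res id, res name, atom name) per atom, for reports."""
        return list(
            zip(
                self.chain_ids.tolist(), self.res_ids.tolist(),
                self.res_names.tolist(), self.atom_names.tolist(),
            )
        )

    def diameter(self) -> float:
        if len(self) == 1:
            return 0.0
        return float(cdist(self.coords, self.coords).max())

    # -- patch exchange format (TSV) --------------------------------------
    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chain": self.chain_ids,
                "resnum": self.res_ids,
                "resname": self.res_names,
                "atomname": self.atom_names,
                "x": np.round(self.coords[:, 0], 3),
                "y": np.round(self.coords[:, 1], 3),
                "z": np.round(self.coords[:, 2], 3),
                "label": self.labels,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SurfacePatch":
        df = pd.read_csv(path, sep="\t", dtype={"chain": str})
        required = {"chain", "resnum", "resname", "atomname", "x", "y", "z", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"patch TSV {path} missing columns {sorted(missing)}")
        atom_names = df["atomname"].astype(str).to_numpy()
        return cls(
            coords=df[["x", "y", "z"]].to_numpy(dtype=float),
            chain_ids=df["chain"].astype(str).to_numpy(),
            res_ids=df["resnum"].to_numpy(dtype=int),
            res_names=df["resname"].astype(str).to_numpy(),
            atom_names=atom_names,
            elements=np.array([guess_element(a) for a in atom_names]),
            labels=df["label"].astype(str).to_numpy(),
            source=str(path),
        )


def guess_element(atom_name: str) -> str:
    """Element symbol from a PDB atom name (first alphabetic character,
    honoring the common two-letter cases)."""
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        return "X"
    two = name[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "MN", "SE", "NA"):
        return two.capitalize()
    return name[0].upper()


def _locate_bad_record(path) -> int | None:
    """First 1-based line number of an unparseable ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    return lineno
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    return lineno
    return None


def read_structure(path) -> struc.AtomArray:
    """Read a PDB file into an atom array (model 1, altlocs resolved by
    occupancy).  Waters and hydrogens are kept; downstream extraction drops
    them by default."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            atoms = pdb.get_structure(
                model=1, altloc="occupancy", extra_fields=["occupancy"]
            )
    except Exception as exc:
        raise ParseError(
            f"could not parse PDB file {path}: {exc}", line=_locate_bad_record(path)
        ) from exc
    if atoms.array_length() == 0:
        raise ParseError(f"no ATOM/HETATM records in {path}")
    return atoms


def _is_water(atoms: struc.AtomArray) -> np.ndarray:
    return np.isin(atoms.res_name, ("HOH", "WAT", "DOD"))


def extract_binding_site(
    atoms: struc.AtomArray,
    ligand: str,
    chain: str | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    include_hydrogens: bool = False,
    include_waters: bool = False,
) -> SurfacePatch:
    """All protein atoms within ``cutoff`` Å of any atom of the ligand.

    The ligand is selected by HETATM residue name, optionally qualified by
    chain; with several copies and no qualifier the first chain in file
    order is used (with a warning).  The distance test is atom center to
    atom center, boundary inclusive.  By default only heavy protein atoms
    count and waters are excluded.
    """
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")
    lig_mask = atoms.hetero & (atoms.res_name == ligand) & ~_is_water(atoms)
    if chain is not None:
        lig_mask &= atoms.chain_id == chain
    if not lig_mask.any():
        available = sorted(set(atoms.res_name[atoms.hetero & ~_is_water(atoms)].tolist()))
        raise LigandNotFoundError(ligand if chain is None else f"{ligand}/{chain}", available)
    lig_chains = atoms.chain_id[lig_mask]
    first_chain = lig_chains[0]
    if chain is None and len(set(lig_chains.tolist())) > 1:
        logger.warning(
            "ligand %s present in chains %s; using chain %s",
            ligand, sorted(set(lig_chains.tolist())), first_chain,
        )
        lig_mask &= atoms.chain_id == first_chain
    lig_coords = atoms.coord[lig_mask]

    prot_mask = ~atoms.hetero
    if not include_waters:
        prot_mask &= ~_is_water(atoms)
    if not include_hydrogens:
        prot_mask &= ~np.isin(atoms.element, ("H", "D"))
    prot = atoms[prot_mask]
    if prot.array_length() == 0:
        raise InvalidArgumentError("structure has no protein atoms")

    dmin = cdist(prot.coord, lig_coords).min(axis=1)
    shell = prot[dmin <= cutoff]
    if shell.array_length() == 0:
        raise InvalidArgumentError(
            f"no protein atoms within {cutoff} Å of ligand {ligand}"
        )

    # drop duplicate atoms (same chain/residue/atom name after altloc resolution)
    keys = list(zip(shell.chain_id.tolist(), shell.res_id.tolist(),
                    shell.ins_code.tolist(), shell.atom_name.tolist()))
    seen: set = set()
    keep = np.ones(len(keys), dtype=bool)
    for i, k in enumerate(keys):
        if k in seen:
            keep[i] = False
        else:
            seen.add(k)
    shell = shell[keep]

    return SurfacePatch(
        coords=shell.coord.astype(float),
        chain_ids=shell.chain_id.astype(str),
        res_ids=shell.res_id.astype(int),
        res_names=shell.res_name.astype(str),
        atom_names=shell.atom_name.astype(str),
        elements=shell.element.astype(str),
        labels=np.full(shell.array_length(), "NONE", dtype=object),
        source=f"ligand={ligand} chain={chain or first_chain} cutoff={cutoff}",
    )


@lru_cache(maxsize=1)
def load_typing_table() -> dict[tuple[str, str], str]:
    """The shipped (residue name, atom name) -> label table."""
    with resources.files("sitealign.data").joinpath("atom_types.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    table = {}
    for row in df.itertuples(index=False):
        table[(str(row.resname), str(row.atomname))] = str(row.label)
    return table


def assign_atom_properties(patch: SurfacePatch) -> SurfacePatch:
    """Label every atom by table lookup, falling back to element rules.

    Lookup order: (residue, atom) row, then the backbone wildcard row
    ("*", atom), then the element fallback (N -> DO, O -> ACC, C/S -> ALI).
    Unknown atoms get NONE with a logged warning.  Pure and idempotent.
    """
    table = load_typing_table()
    labels = np.empty(len(patch), dtype=object)
    for i in range(len(patch)):
        res = str(patch.res_names[i])
        atom = str(patch.atom_names[i])
        label = table.get((res, atom)) or table.get(("*", atom))
        if label is None:
            label = _ELEMENT_FALLBACK.get(str(patch.elements[i]).upper())
        if label is None:
            logger.warning("atom %s/%s %s has no known class; labeling NONE", res, patch.res_ids[i], atom)
            label = "NONE"
        labels[i] = label
    return replace(patch, labels=labels)
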