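"""Protein structure model and rigid-body geometry.

A :class:`Structure` is an ordered list of residues, each reduced to the two
points the descriptor machinery needs: the Cα position and the geometric
center of the side-chain heavy atoms.  Multi-chain entries are concatenated
into one ordered residue list, but sequence neighborhood never crosses a
chain boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: backbone atoms excluded from the side-chain geometric center
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue reduced to its descriptor-relevant geometry.

    ``sc_center`` is the unweighted mean of side-chain heavy atoms; for
    glycine (or a residue with no resolved side-chain atoms) it equals the
    Cα position, so every residue remains contact-evaluable.
    """

    id: ResidueId
    aa: str
    ca: np.ndarray
    sc_center: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        object.__setattr__(self, "sc_center", np.asarray(self.sc_center, dtype=float))
        if not (np.all(np.isfinite(self.ca)) and np.all(np.isfinite(self.sc_center))):
            raise ValueError(f"non-finite coordinates for residue {self.id}")


class Structure:
    """Ordered residues of one or more protein chains.

    Residue ordinals are 0-based and contiguous; user-facing output keeps
    the PDB's own numbering through :attr:`Residue.id`.
    """

    def __init__(self, name: str, residues: Sequence[Residue]):
        self.name = name
        self.residues = list(residues)
        self.index: dict[ResidueId, int] = {}
        for i, r in enumerate(self.residues):
            if r.id in self.index:
                raise ValueError(f"duplicate residue id {r.id} in {name}")
            self.index[r.id] = i
        self.ca = (
            np.array([r.ca for r in self.residues], dtype=float).reshape(-1, 3)
            if self.residues
            else np.zeros((0, 3))
        )
        self.sc = (
            np.array([r.sc_center for r in self.residues], dtype=float).reshape(-1, 3)
            if self.residues
            else np.zeros((0, 3))
        )
        self.chain_ids = [r.id[0] for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)

    def __repr__(self) -> str:
        return f"Structure({self.name!r}, {len(self)} residues)"

    def same_chain(self, i: int, j: int) -> bool:
        return self.chain_ids[i] == self.chain_ids[j]

    def window_valid(self, center: int, half: int = 2) -> bool:
        """True if ``center ± half`` stays inside the chain of ``center``."""
        lo, hi = center - half, center + half
        if lo < 0 or hi >= len(self):
            return False
        return self.chain_ids[lo] == self.chain_ids[center] == self.chain_ids[hi]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly transformed copy (x -> R x + t)."""
        res = [
            Residue(r.id, r.aa, rotation @ r.ca + translation, rotation @ r.sc_center + translation)
            for r in self.residues
        ]
        return Structure(self.name, res)


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid transform of one point set onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


class StructureError(ValueError):
    """Raised for unreadable or empty structure inputs."""


def sidechain_center(atoms: dict[str, np.ndarray], ca: np.ndarray | None = None) -> np.ndarray:
    """Geometric center of the side-chain heavy atoms.

    Parameters
    ----------
    atoms
        Mapping of atom name to 3D coordinate.  Backbone atoms
        (N, CA, C, O, OXT) and hydrogens are excluded.
    ca
        Fallback Cα position used when no side-chain atom remains
        (glycine, or unresolved side chain).
    """
    side = [
        xyz
        for name, xyz in atoms.items()
        if name not in BACKBONE_ATOMS and not name.startswith("H") and not name.startswith("D")
    ]
    if not side:
        if ca is None and "CA" not in atoms:
            raise ValueError("no side-chain atoms and no CA fallback")
        return np.asarray(ca if ca is not None else atoms["CA"], dtype=float)
    return np.mean(np.asarray(side, dtype=float), axis=0)


def read_structure(path: str | Path, chains: Iterable[str] | None = None, name: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Uses the first MODEL only; altloc is resolved per atom to the highest
    occupancy (first on ties); residues without a Cα are skipped with a
    warning; non-amino HETATM records are ignored.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    wanted = set(chains) if chains is not None else None
    residues: list[Residue] = []
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            # altloc: keep highest occupancy per atom name, first wins ties
            atoms: dict[str, tuple[float, np.ndarray]] = {}
            for atom in res:
                occ = atom.occ
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if atom.name not in atoms or occ > atoms[atom.name][0]:
                    atoms[atom.name] = (occ, pos)
            coords = {n: p for n, (_, p) in atoms.items()}
            if "CA" not in coords:
                log.warning("skipping residue %s %s%s: no CA atom", res.name, chain.name, res.seqid.num)
                continue
            rid: ResidueId = (chain.name, res.seqid.num, res.seqid.icode.strip() or "")
            aa = gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
            if not aa.isalpha():
                aa = "X"
            residues.append(Residue(rid, aa, coords["CA"], sidechain_center(coords, coords["CA"])))
    if not residues:
        raise StructureError(f"no amino-acid residues with CA in {path} (chains={chains})")
    return Structure(name or path.stem, residues)


_AA3 = {"A": "ALA", "G": "GLY", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR", "X": "UNK"}


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a geometry-summary PDB: CA plus a CB pseudo-atom at the
    side-chain center (omitted when it coincides with Cα).

    Round-trips through :func:`read_structure`: ids, order, Cα and
    side-chain-center coordinates are all preserved.
    """
    lines = []
    serial = 1
    for r in structure.residues:
        resname = _AA3.get(r.aa, "UNK")
        chain, num, icode = r.id
        for atom_name, xyz in (("CA", r.ca), ("CB", r.sc_center)):
            if atom_name == "CB" and np.allclose(r.sc_center, r.ca):
                continue
            lines.append(
                "ATOM  "
                + f"{serial:5d}"
                + f"  {atom_name:<3s}"  # cols 13-16, short names offset by one
                + " "  # altloc
                + f"{resname:>3s}"
                + " "
                + f"{chain[:1]:1s}"
                + f"{num:4d}"
                + f"{icode or ' ':1s}"
                + "   "
                + f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                + f"{1.0:6.2f}{0.0:6.2f}"
                + " " * 10
                + f"{'C':>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Optimal least-squares rigid superposition of ``coords_b`` onto
    ``coords_a`` (Kabsch).  Reflections are excluded: the returned rotation
    is always proper.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if len(a) < 1:
        raise ValueError("empty point sets")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca_, b - cb_
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = b0 @ rot.T - a0
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    trans = ca_ - rot @ cb_
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def batch_rmsd(windows_a: np.ndarray, windows_b: np.ndarray) -> np.ndarray:
    """RMSD of many same-length point-set pairs after optimal superposition.

    ``windows_a``/``windows_b`` have shape (m, k, 3); returns shape (m,).
    Uses the Kabsch singular-value identity, batched.
    """
    a = np.asarray(windows_a, dtype=float)
    b = np.asarray(windows_b, dtype=float)
    k = a.shape[1]
    a0 = a - a.mean(axis=1, keepdims=True)
    b0 = b - b.mean(axis=1, keepdims=True)
    h = np.einsum("mki,mkj->mij", b0, a0)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("mij,mjk->mik", np.transpose(vt, (0, 2, 1)), np.transpose(u, (0, 2, 1))))
    s_sum = s[:, 0] + s[:, 1] + np.sign(det) * s[:, 2]
    e0 = np.sum(a0 * a0, axis=(1, 2)) + np.sum(b0 * b0, axis=(1, 2))
    msd = np.maximum(e0 - 2.0 * s_sum, 0.0) / k
    return np.sqrt(msd)


def rotation_angle(r1: np.ndarray, r2: np.ndarray) -> float:
    """Angle in [0, π] of the relative rotation r1·r2ᵀ.

    Symmetric in its arguments; raises for non-orthogonal input.
    """
    for r in (r1, r2):
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
            raise ValueError("input is not a proper rotation")
    rel = r1 @ r2.T
    c = (np.trace(rel) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))
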