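"""Reading protein-ligand complexes and extracting binding sites.

A complex is a protein (PDB) plus a ligand (MOL2/SDF) with an optional
experimental binding strength on the -log K_d/i scale.  The binding site
("binding area") is every ligand atom together with every protein atom
within a distance cutoff (default 4 Angstrom) of any ligand atom; only
those atoms become graph nodes downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "ComplexStructure",
    "BindingSite",
    "StructureParseError",
    "EmptyStructureError",
    "read_protein",
    "read_ligand",
    "load_complex",
    "extract_binding_site",
    "read_complex_index",
]

#: residue names treated as water and always removed
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """A structure file could not be parsed."""


class EmptyStructureError(StructureParseError):
    """Parsing succeeded but no atoms survived filtering."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom (or hydrogen, if retained) of one molecule.

    ``origin`` records which molecule the atom came from; inter-molecular
    edges are defined only between atoms of different origin.
    """

    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    origin: Literal["protein", "ligand"]
    serial: int
    residue_tag: Optional[str] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be 3 finite reals")
        object.__setattr__(self, "coords", coords)
        if self.origin not in ("protein", "ligand"):
            raise ValueError(f"invalid origin {self.origin!r}")


@dataclass
class ComplexStructure:
    """One protein-ligand complex: ordered atoms plus an optional label."""

    complex_id: str
    atoms: list[Atom]
    label: Optional[float] = None
    # RDKit molecules retained for chemistry perception; atom order in each
    # molecule matches the order of same-origin atoms in ``atoms``.
    protein_mol: object = field(default=None, repr=False)
    ligand_mol: object = field(default=None, repr=False)
    extras: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        origins = {a.origin for a in self.atoms}
        if origins != {"protein", "ligand"}:
            raise ValueError(
                f"{self.complex_id}: complex needs at least one protein and one ligand atom"
            )

    @property
    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.origin == "ligand"]

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.origin == "protein"]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class BindingSite:
    """Binding-area atoms (ligand block first) with their distance matrix."""

    atoms: list[Atom]
    origin_mask: np.ndarray  # True where the atom is a ligand atom
    distance_matrix: np.ndarray  # n x n, Angstrom
    parent_indices: np.ndarray  # index of each site atom in the parent complex
    cutoff: float

    @property
    def n(self) -> int:
        return len(self.atoms)


def _filter_pdb_lines(text: str, path: str) -> list[str]:
    """Keep ATOM/HETATM records, dropping waters and non-primary altLocs."""
    kept = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureParseError(
                f"{path}:{lineno}: truncated coordinate record: {line!r}"
            )
        resname = line[17:20].strip().upper()
        if resname in WATER_RESIDUES:
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        kept.append(line)
    return kept


def _mol_to_atoms(mol, origin: str) -> list[Atom]:
    conf = mol.GetConformer()
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        info = a.GetPDBResidueInfo()
        serial = info.GetSerialNumber() if info is not None else i + 1
        tag = None
        if origin == "protein" and info is not None:
            tag = f"{info.GetResidueName().strip()}{info.GetResidueNumber()}"
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                origin=origin,
                serial=serial,
                residue_tag=tag,
            )
        )
    return atoms


def _sanitize_lenient(mol) -> None:
    """Best-effort sanitization: valence problems degrade, they do not abort."""
    from rdkit import Chem

    try:
        Chem.SanitizeMol(mol)
    except Exception:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
            catchErrors=True,
        )


def read_protein(path, strip_hydrogens: bool = True, return_mol: bool = False):
    """Read a protein PDB file into a list of atoms (``origin='protein'``).

    Waters and non-primary alternate locations are removed; cofactors and
    ions in HETATM records are kept as protein atoms.  File order is
    preserved.  With ``return_mol=True`` the RDKit molecule used for
    chemistry perception is returned alongside the atom list.
    """
    from rdkit import Chem

    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc
    lines = _filter_pdb_lines(text, str(path))
    if not lines:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records after filtering")
    block = "\n".join(lines) + "\n"
    mol = Chem.MolFromPDBBlock(
        block, sanitize=False, removeHs=strip_hydrogens, proximityBonding=True
    )
    if mol is None or mol.GetNumAtoms() == 0:
        raise EmptyStructureError(f"{path}: no atoms after hydrogen filtering")
    _sanitize_lenient(mol)
    atoms = _mol_to_atoms(mol, "protein")
    if strip_hydrogens:
        keep = [i for i, a in enumerate(atoms) if a.element != "H"]
        if len(keep) != len(atoms):  # RDKit keeps e.g. bridging hydrogens
            atoms = [atoms[i] for i in keep]
    if not atoms:
        raise EmptyStructureError(f"{path}: zero heavy atoms")
    return (atoms, mol) if return_mol else atoms


def read_ligand(
    path,
    format: Optional[str] = None,
    strip_hydrogens: bool = True,
    return_mol: bool = False,
):
    """Read a ligand MOL2/SDF file into atoms (``origin='ligand'``).

    ``format`` is inferred from the suffix when omitted.  A multi-record
    SDF yields its first molecule with a warning.  The bond table stays on
    the returned RDKit molecule for chemistry perception.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"cannot read {path}: file not found")
    if format is None:
        format = path.suffix.lstrip(".").lower()
        if format == "mol":
            format = "sdf"
    if format not in ("mol2", "sdf"):
        raise StructureParseError(f"{path}: unsupported ligand format {format!r}")

    if format == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=strip_hydrogens)
        if mol is None:
            raise StructureParseError(f"{path}: not parseable as MOL2")
        _sanitize_lenient(mol)
    else:
        try:
            supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=strip_hydrogens)
            mols = [m for m in supplier if m is not None]
        except OSError as exc:
            raise EmptyStructureError(f"{path}: not parseable as SDF ({exc})") from exc
        if not mols:
            raise EmptyStructureError(f"{path}: no molecule records parseable as SDF")
        if len(mols) > 1:
            warnings.warn(f"{path}: {len(mols)} records, taking the first")
        mol = mols[0]
        _sanitize_lenient(mol)
    if strip_hydrogens:
        mol = Chem.RemoveHs(mol, sanitize=False)
    if mol.GetNumAtoms() == 0:
        raise EmptyStructureError(f"{path}: ligand has zero atoms after filtering")
    atoms = _mol_to_atoms(mol, "ligand")
    return (atoms, mol) if return_mol else atoms


def load_complex(
    complex_id: str,
    protein_path,
    ligand_path,
    label: Optional[float] = None,
    ligand_format: Optional[str] = None,
    strip_hydrogens: bool = True,
) -> ComplexStructure:
    """Read both molecules and merge them (ligand atoms follow protein atoms)."""
    protein_atoms, pmol = read_protein(
        protein_path, strip_hydrogens=strip_hydrogens, return_mol=True
    )
    ligand_atoms, lmol = read_ligand(
        ligand_path, format=ligand_format, strip_hydrogens=strip_hydrogens, return_mol=True
    )
    return ComplexStructure(
        complex_id=complex_id,
        atoms=protein_atoms + ligand_atoms,
        label=label,
        protein_mol=pmol,
        ligand_mol=lmol,
    )


def extract_binding_site(complex: ComplexStructure, cutoff: float = 4.0) -> BindingSite:
    """All ligand atoms plus protein atoms within ``cutoff`` of any ligand atom.

    The boundary is inclusive (d <= cutoff).  Site atoms are ordered ligand
    block first, then retained protein atoms, both in file order, so the
    node ordering (and every tensor built from it) is reproducible.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_idx = [i for i, a in enumerate(complex.atoms) if a.origin == "ligand"]
    prot_idx = [i for i, a in enumerate(complex.atoms) if a.origin == "protein"]
    coords = complex.coords_array()
    dists = cdist(coords[prot_idx], coords[lig_idx])
    keep_prot = [prot_idx[r] for r in range(len(prot_idx)) if dists[r].min() <= cutoff]
    if not keep_prot:
        warnings.warn(
            f"{complex.complex_id}: empty pocket, no protein atom within {cutoff} A"
        )
    order = lig_idx + keep_prot
    site_coords = coords[order]
    D = cdist(site_coords, site_coords)
    atoms = [complex.atoms[i] for i in order]
    mask = np.array([a.origin == "ligand" for a in atoms], dtype=bool)
    return BindingSite(
        atoms=atoms,
        origin_mask=mask,
        distance_matrix=D,
        parent_indices=np.array(order, dtype=int),
        cutoff=cutoff,
    )


def read_complex_index(path) -> list[dict]:
    """Read a tab-separated complex index.

    Columns: complex_id, protein_path, ligand_path, label ('' or '-' for
    unlabeled); '#' starts a comment.  Relative paths are resolved against
    the index file's directory.
    """
    path = Path(path)
    base = path.parent
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        label: Optional[float] = None
        if len(parts) >= 4 and parts[3].strip() not in ("", "-"):
            label = float(parts[3])
        rows.append(
            {
                "complex_id": parts[0].strip(),
                "protein_path": str((base / parts[1].strip())),
                "ligand_path": str((base / parts[2].strip())),
                "label": label,
            }
        )
    return rows
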