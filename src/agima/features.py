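"""Node-feature sets for binding-site atoms.

Four named sets are supported:

* ``F18`` -- 9-way one-hot atom type (B, C, N, O, P, S, Se, halogen,
  metal), hybridization code, heavy/hetero neighbor counts, five binary
  pharmacophoric flags (hydrophobic, aromatic, H-bond acceptor, H-bond
  donor, ring membership) and the partial charge.
* ``F8`` -- pharmacophoric flags (hydrophobic, aromatic, acceptor, donor,
  metallicity) plus positive charge, negative charge and excluded volume.
* ``F13`` -- ``F18`` without the five pharmacophoric flags.
* ``F21`` -- the non-redundant union of the three: ``F18`` plus the three
  ``F8`` members (positive/negative charge, excluded volume) that are not
  already covered.

Positive/negative charge are the positive/negative parts of the Gasteiger
partial charge; excluded volume is the van-der-Waals sphere volume
(4/3)*pi*r^3 in cubic Angstrom with Bondi-type radii.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structures import BindingSite, ComplexStructure

__all__ = [
    "AtomChemistry",
    "FeatureSetSpec",
    "NodeFeatureMatrix",
    "ChemistryPerceptionError",
    "FEATURE_SETS",
    "get_feature_set",
    "perceive_chemistry",
    "element_default_chemistry",
    "featurize",
]

HALOGENS = {"F", "Cl", "Br", "I", "At"}
#: common biologically relevant metals; any other element RDKit's periodic
#: table knows as metallic is classified the same way at featurization time
METALS = {"Na", "K", "Mg", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Cd", "Hg"}

_ONE_HOT_ELEMENTS = ["B", "C", "N", "O", "P", "S", "Se"]


class ChemistryPerceptionError(RuntimeError):
    """Chemistry perception failed for one complex (carries its id)."""

    def __init__(self, complex_id: str, message: str):
        super().__init__(f"{complex_id}: {message}")
        self.complex_id = complex_id


@dataclass
class AtomChemistry:
    """Perceived chemical attributes of one atom."""

    hybridization: int  # 1=sp, 2=sp2, 3=sp3, 0=other
    heavy_neighbors: int
    hetero_neighbors: int
    hydrophobic: bool
    aromatic: bool
    hb_acceptor: bool
    hb_donor: bool
    in_ring: bool
    is_metal: bool
    partial_charge: float  # e
    vdw_radius: float  # Angstrom

    def __post_init__(self) -> None:
        if self.heavy_neighbors < 0 or self.hetero_neighbors < 0:
            raise ValueError("neighbor counts must be non-negative")
        if not math.isfinite(self.partial_charge):
            raise ValueError("partial charge must be finite")
        if self.vdw_radius <= 0:
            raise ValueError("vdW radius must be positive")


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    feature_names: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.feature_names)


_F18_NAMES = (
    "atom_type_B",
    "atom_type_C",
    "atom_type_N",
    "atom_type_O",
    "atom_type_P",
    "atom_type_S",
    "atom_type_Se",
    "atom_type_halogen",
    "atom_type_metal",
    "hybridization",
    "heavy_neighbors",
    "hetero_neighbors",
    "hydrophobic",
    "aromatic",
    "hb_acceptor",
    "hb_donor",
    "in_ring",
    "partial_charge",
)
_F8_NAMES = (
    "hydrophobic",
    "aromatic",
    "hb_acceptor",
    "hb_donor",
    "is_metal",
    "positive_charge",
    "negative_charge",
    "excluded_volume",
)
_F13_NAMES = tuple(n for n in _F18_NAMES if n not in _F18_NAMES[12:17])
_F21_NAMES = _F18_NAMES + ("positive_charge", "negative_charge", "excluded_volume")

FEATURE_SETS = {
    "F18": FeatureSetSpec("F18", _F18_NAMES),
    "F8": FeatureSetSpec("F8", _F8_NAMES),
    "F13": FeatureSetSpec("F13", _F13_NAMES),
    "F21": FeatureSetSpec("F21", _F21_NAMES),
}


def get_feature_set(name: str) -> FeatureSetSpec:
    try:
        return FEATURE_SETS[name]
    except KeyError:
        raise KeyError(f"unknown feature set {name!r}; choose from {sorted(FEATURE_SETS)}")


@dataclass
class NodeFeatureMatrix:
    values: np.ndarray  # n x m
    feature_names: tuple[str, ...]
    set_name: str

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def _is_metal(symbol: str) -> bool:
    if symbol in METALS:
        return True
    if symbol in HALOGENS or symbol in _ONE_HOT_ELEMENTS or symbol == "H":
        return False
    try:
        from rdkit import Chem

        pt = Chem.GetPeriodicTable()
        z = pt.GetAtomicNumber(symbol)
    except Exception:
        return False
    # metallic blocks of the periodic table (alkali through post-transition)
    metal_z = set(range(3, 5)) | set(range(11, 14)) | set(range(19, 32)) | set(
        range(37, 51)
    ) | set(range(55, 85)) | set(range(87, 118))
    nonmetal_z = {5, 6, 7, 8, 9, 10, 14, 15, 16, 17, 18, 32, 33, 34, 35, 36, 51, 52, 53, 54, 84, 85}
    return z in metal_z - nonmetal_z


def _hybridization_code(rd_atom) -> int:
    from rdkit.Chem import HybridizationType

    return {
        HybridizationType.SP: 1,
        HybridizationType.SP2: 2,
        HybridizationType.SP3: 3,
    }.get(rd_atom.GetHybridization(), 0)


def _perceive_mol(mol, complex_id: str) -> list[AtomChemistry]:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    pt = Chem.GetPeriodicTable()
    try:
        AllChem.ComputeGasteigerCharges(mol, throwOnParamFailure=False)
    except Exception as exc:
        raise ChemistryPerceptionError(complex_id, f"Gasteiger charges failed: {exc}")

    records = []
    nan_charges = 0
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        neighbors = list(atom.GetNeighbors())
        heavy = [nb for nb in neighbors if nb.GetAtomicNum() > 1]
        hetero = [nb for nb in heavy if nb.GetSymbol() not in ("C", "H")]
        charge = (
            atom.GetDoubleProp("_GasteigerCharge")
            if atom.HasProp("_GasteigerCharge")
            else None
        )
        if charge is None or not math.isfinite(charge):
            nan_charges += 1
            charge = 0.0
        aromatic = atom.GetIsAromatic()
        n_h = atom.GetTotalNumHs(includeNeighbors=True)
        # simple rule-based pharmacophore typing (documented defaults):
        # donors/acceptors are N/O with/without attached hydrogens;
        # hydrophobic atoms are carbons with no N/O neighbor plus thioether S
        is_no = symbol in ("N", "O")
        donor = is_no and n_h >= 1
        acceptor = is_no and atom.GetFormalCharge() <= 0
        no_neighbor = any(nb.GetSymbol() in ("N", "O") for nb in neighbors)
        hydrophobic = (symbol == "C" and not no_neighbor) or (
            symbol == "S" and len(heavy) == 2 and all(nb.GetSymbol() == "C" for nb in heavy)
        )
        records.append(
            AtomChemistry(
                hybridization=_hybridization_code(atom),
                heavy_neighbors=len(heavy),
                hetero_neighbors=len(hetero),
                hydrophobic=hydrophobic,
                aromatic=aromatic,
                hb_acceptor=acceptor,
                hb_donor=donor,
                in_ring=atom.IsInRing(),
                is_metal=_is_metal(symbol),
                partial_charge=float(charge),
                vdw_radius=float(pt.GetRvdw(atom.GetAtomicNum())),
            )
        )
    if nan_charges:
        warnings.warn(
            f"{complex_id}: {nan_charges} atoms had undefined Gasteiger charge, set to 0"
        )
    return records


def perceive_chemistry(complex: ComplexStructure) -> list[AtomChemistry]:
    """Per-atom chemistry for every atom of the complex, in atom order.

    Requires the RDKit molecules retained by :func:`agima.structures.load_complex`.
    A failure is reported with the complex id so a batch run can skip the
    complex rather than abort.
    """
    if complex.protein_mol is None or complex.ligand_mol is None:
        raise ChemistryPerceptionError(
            complex.complex_id,
            "no molecule objects attached; load the complex from files or use "
            "element_default_chemistry for in-memory structures",
        )
    prot = _perceive_mol(complex.protein_mol, complex.complex_id)
    lig = _perceive_mol(complex.ligand_mol, complex.complex_id)
    n_prot = len(complex.protein_atoms)
    n_lig = len(complex.ligand_atoms)
    if len(prot) != n_prot or len(lig) != n_lig:
        raise ChemistryPerceptionError(
            complex.complex_id,
            f"atom count mismatch (protein {len(prot)}/{n_prot}, ligand {len(lig)}/{n_lig})",
        )
    prot_iter, lig_iter = iter(prot), iter(lig)
    return [next(lig_iter) if a.origin == "ligand" else next(prot_iter) for a in complex.atoms]


def element_default_chemistry(
    complex: ComplexStructure, partial_charges: Optional[Sequence[float]] = None
) -> list[AtomChemistry]:
    """Chemistry derived from elements alone, for structures without bonds.

    Used for synthetic fixtures, whose atoms are deliberately unbonded.
    Neighbor counts are zero; flags fall back to element identity; charges
    default to the complex's stored ``extras['partial_charges']`` or zero.
    """
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    if partial_charges is None:
        partial_charges = complex.extras.get("partial_charges")
    records = []
    for i, atom in enumerate(complex.atoms):
        q = float(partial_charges[i]) if partial_charges is not None else 0.0
        records.append(
            AtomChemistry(
                hybridization=3 if atom.element == "C" else 0,
                heavy_neighbors=0,
                hetero_neighbors=0,
                hydrophobic=atom.element == "C",
                aromatic=False,
                hb_acceptor=atom.element in ("N", "O"),
                hb_donor=False,
                in_ring=False,
                is_metal=_is_metal(atom.element),
                partial_charge=q,
                vdw_radius=float(pt.GetRvdw(pt.GetAtomicNumber(atom.element))),
            )
        )
    return records


def _one_hot_index(element: str) -> Optional[int]:
    if element in _ONE_HOT_ELEMENTS:
        return _ONE_HOT_ELEMENTS.index(element)
    if element in HALOGENS:
        return 7
    if _is_metal(element):
        return 8
    return None


def _feature_value(name: str, atom, chem: AtomChemistry) -> float:
    if name == "hybridization":
        return float(chem.hybridization)
    if name == "heavy_neighbors":
        return float(chem.heavy_neighbors)
    if name == "hetero_neighbors":
        return float(chem.hetero_neighbors)
    if name == "hydrophobic":
        return float(chem.hydrophobic)
    if name == "aromatic":
        return float(chem.aromatic)
    if name == "hb_acceptor":
        return float(chem.hb_acceptor)
    if name == "hb_donor":
        return float(chem.hb_donor)
    if name == "in_ring":
        return float(chem.in_ring)
    if name == "is_metal":
        return float(chem.is_metal)
    if name == "partial_charge":
        return chem.partial_charge
    if name == "positive_charge":
        return max(chem.partial_charge, 0.0)
    if name == "negative_charge":
        return max(-chem.partial_charge, 0.0)
    if name == "excluded_volume":
        return (4.0 / 3.0) * math.pi * chem.vdw_radius**3
    raise KeyError(name)


def featurize(
    site: BindingSite,
    chem: Sequence[AtomChemistry],
    spec: FeatureSetSpec | str,
) -> NodeFeatureMatrix:
    """Build the n x m node-feature matrix F for a binding site.

    ``chem`` is indexed like the parent complex's atom list (the output of
    :func:`perceive_chemistry`); site atoms select their records through
    ``site.parent_indices``.  A pure function: identical inputs yield a
    bit-identical matrix.
    """
    if isinstance(spec, str):
        spec = get_feature_set(spec)
    n = site.n
    F = np.zeros((n, spec.m), dtype=float)
    unknown = 0
    one_hot_cols = {
        name: j for j, name in enumerate(spec.feature_names) if name.startswith("atom_type_")
    }
    for row, (atom, pi) in enumerate(zip(site.atoms, site.parent_indices)):
        record = chem[pi]
        if one_hot_cols:
            idx = _one_hot_index(atom.element)
            if idx is None:
                unknown += 1
            else:
                F[row, one_hot_cols[_F18_NAMES[idx]]] = 1.0
        for j, name in enumerate(spec.feature_names):
            if name.startswith("atom_type_"):
                continue
            F[row, j] = _feature_value(name, atom, record)
    if unknown:
        warnings.warn(
            f"{unknown} atoms outside the one-hot vocabulary (all-zero type block)"
        )
    return NodeFeatureMatrix(values=F, feature_names=spec.feature_names, set_name=spec.name)


def export_features(matrix: NodeFeatureMatrix, path) -> None:
    """Write F as a tab-separated table with a feature-name header row."""
    header = "\t".join(matrix.feature_names)
    np.savetxt(path, matrix.values, delimiter="\t", header=header, comments="")
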