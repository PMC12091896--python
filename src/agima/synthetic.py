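"""Synthetic binding-site fixtures with exactly controlled contact counts.

A toy complex is a compact cluster of ligand atoms surrounded by protein
atoms placed so that the number of inter-molecular contacts realized in
each distance range -- (2, 3] and (3, 4] Angstrom -- equals a requested
target exactly; remaining protein atoms sit beyond the binding cutoff.
Several protein atoms may contact the same ligand atom, so node degrees
vary across complexes, which is what lets the normalized convolution
carry per-range contact information into the pooled embeddings.

Labeled datasets assign each complex a binding strength that is linear in
its per-range contact counts (plus Gaussian noise), optionally modulated
by the partial-charge feature of the contacted ligand atoms.  Such labels
are representable by the one-hop convolution architecture, which makes
recovery of the per-range weights a fair end-to-end check of the learning
machinery.  The fixtures deliberately mimic nothing else about real
complexes: no folds, no bonds, no chemistry beyond element labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .graphs import build_adjacency_tensor, get_scheme
from .structures import Atom, ComplexStructure, extract_binding_site

__all__ = [
    "FixtureSpec",
    "SyntheticTaskSpec",
    "GenerationError",
    "make_toy_complex",
    "make_labeled_dataset",
    "write_complex_files",
    "write_dataset",
]

_MIN_SEP = 2.2  # Angstrom; also keeps reloaded PDBs free of spurious proximity bonds
_SITE_CUTOFF = 4.0


class GenerationError(RuntimeError):
    """Geometry could not be satisfied within the retry budget."""


@dataclass
class FixtureSpec:
    """Targets for one toy complex.

    ``element_palette[0]`` labels ligand atoms, ``element_palette[1]``
    protein atoms; distinct elements give the convolution a way to tell
    the two molecules apart.
    """

    n_ligand_atoms: int = 6
    n_protein_atoms: int = 8
    contacts_range1: int = 2  # target pairs in (2, 3] A
    contacts_range2: int = 2  # target pairs in (3, 4] A
    element_palette: tuple[str, ...] = ("C", "N")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligand_atoms < 1 or self.n_protein_atoms < 1:
            raise ValueError("need at least one atom per molecule")
        if self.contacts_range1 + self.contacts_range2 > self.n_protein_atoms:
            raise ValueError("more contacts requested than protein atoms")
        if len(self.element_palette) < 2:
            raise ValueError("element_palette needs ligand and protein symbols")


@dataclass
class SyntheticTaskSpec:
    """A labeled regression task over toy complexes.

    label = weight_range1 * c1 + weight_range2 * c2 + N(0, noise_sd), with
    c1/c2 the realized per-range contact counts.  When
    ``feature_modulation='partial_charge'`` each contact contributes its
    ligand atom's charge instead of 1, the counts are held fixed, and the
    charge column becomes the only label-relevant feature.
    """

    n_complexes: int = 400
    weight_range1: float = 1.0
    weight_range2: float = 0.2
    noise_sd: float = 0.1
    feature_modulation: Optional[str] = None
    seed: int = 0
    n_ligand_atoms: int = 6
    max_contacts_per_range: int = 8
    extra_protein_atoms: int = 3
    fixed_contacts: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.feature_modulation not in (None, "partial_charge"):
            raise ValueError("feature_modulation supports only 'partial_charge'")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _place_ligand(rng: np.random.Generator, n: int) -> np.ndarray:
    radius = 2.2 * n ** (1 / 3) + 1.5
    coords: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(500):
            p = rng.uniform(-radius, radius, size=3)
            if all(np.linalg.norm(p - q) >= _MIN_SEP for q in coords):
                coords.append(p)
                break
        else:
            raise GenerationError("could not place ligand cluster")
    return np.array(coords)


def _place_contact(
    rng: np.random.Generator,
    lig: np.ndarray,
    placed: list[np.ndarray],
    lo: float,
    hi: float,
) -> tuple[np.ndarray, int]:
    """A protein atom contacting exactly one ligand atom, in (lo, hi]."""
    n_lig = lig.shape[0]
    for _attempt in range(2000):
        li = int(rng.integers(n_lig))
        d = rng.uniform(lo + 0.1, hi - 0.05)
        pos = lig[li] + d * _random_unit(rng)
        dists = np.linalg.norm(lig - pos, axis=1)
        others = np.delete(dists, li)
        if others.size and others.min() <= _SITE_CUTOFF + 0.05:
            continue  # would create a second contact or join the site twice
        if any(np.linalg.norm(pos - q) < _MIN_SEP for q in placed):
            continue
        return pos, li
    raise GenerationError(f"could not place a contact atom in ({lo}, {hi}]")


def _place_far(
    rng: np.random.Generator, lig: np.ndarray, placed: list[np.ndarray]
) -> np.ndarray:
    n_lig = lig.shape[0]
    for _attempt in range(2000):
        li = int(rng.integers(n_lig))
        pos = lig[li] + rng.uniform(4.6, 7.0) * _random_unit(rng)
        if np.linalg.norm(lig - pos, axis=1).min() <= _SITE_CUTOFF + 0.05:
            continue
        if any(np.linalg.norm(pos - q) < _MIN_SEP for q in placed):
            continue
        return pos
    raise GenerationError("could not place a distant protein atom")


def make_toy_complex(spec: FixtureSpec) -> ComplexStructure:
    """Generate one toy complex whose realized contact counts match the spec.

    The realized adjacency is verified against the graph builder before
    returning; ``extras['contacts']`` records, per contact protein atom,
    the ligand atom index and the range index it realizes.
    """
    last_err: Optional[Exception] = None
    for round_ in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, round_]))
        try:
            return _try_make(spec, rng)
        except GenerationError as exc:
            last_err = exc
    raise GenerationError(f"fixture generation failed after retries: {last_err}")


def _try_make(spec: FixtureSpec, rng: np.random.Generator) -> ComplexStructure:
    lig = _place_ligand(rng, spec.n_ligand_atoms)
    placed: list[np.ndarray] = []
    contacts: list[tuple[int, int]] = []  # (ligand atom index, range index)
    for _ in range(spec.contacts_range1):
        pos, li = _place_contact(rng, lig, placed, 2.0, 3.0)
        placed.append(pos)
        contacts.append((li, 0))
    for _ in range(spec.contacts_range2):
        pos, li = _place_contact(rng, lig, placed, 3.0, 4.0)
        placed.append(pos)
        contacts.append((li, 1))
    n_far = spec.n_protein_atoms - len(placed)
    for _ in range(n_far):
        placed.append(_place_far(rng, lig, placed))

    lig_el, prot_el = spec.element_palette[0], spec.element_palette[1]
    atoms = [
        Atom(element=lig_el, coords=lig[i], origin="ligand", serial=i + 1)
        for i in range(spec.n_ligand_atoms)
    ]
    atoms += [
        Atom(
            element=prot_el,
            coords=placed[j],
            origin="protein",
            serial=j + 1,
            residue_tag=f"UNK{j + 1}",
        )
        for j in range(len(placed))
    ]
    cs = ComplexStructure(
        complex_id=f"toy-{spec.seed}",
        atoms=atoms,
        extras={"contacts": contacts, "fixture_spec": spec},
    )
    # self-verification: the realized tensor must match the targets exactly
    site = extract_binding_site(cs, _SITE_CUTOFF)
    tensor = build_adjacency_tensor(site, get_scheme("AGIMA_2"))
    counts = [int(tensor.slices[:, :, k].sum()) // 2 for k in range(2)]
    if counts != [spec.contacts_range1, spec.contacts_range2]:
        raise GenerationError(
            f"realized contacts {counts} != targets "
            f"{[spec.contacts_range1, spec.contacts_range2]}"
        )
    return cs


def make_labeled_dataset(task: SyntheticTaskSpec) -> list[tuple[ComplexStructure, float]]:
    """Generate ``task.n_complexes`` labeled toy complexes, bit-reproducibly."""
    rng = np.random.default_rng(task.seed)
    out = []
    for i in range(task.n_complexes):
        if task.fixed_contacts is not None:
            c1, c2 = task.fixed_contacts
        elif task.feature_modulation is not None:
            c1 = c2 = max(1, task.max_contacts_per_range // 2)
        else:
            c1 = int(rng.integers(0, task.max_contacts_per_range + 1))
            c2 = int(rng.integers(0, task.max_contacts_per_range + 1))
        spec = FixtureSpec(
            n_ligand_atoms=task.n_ligand_atoms,
            n_protein_atoms=c1 + c2 + task.extra_protein_atoms,
            contacts_range1=c1,
            contacts_range2=c2,
            seed=int(rng.integers(2**31)),
        )
        cs = make_toy_complex(spec)
        cs.complex_id = f"syn-{task.seed}-{i:04d}"
        weights = (task.weight_range1, task.weight_range2)
        if task.feature_modulation == "partial_charge":
            charges = np.zeros(len(cs.atoms))
            q = rng.uniform(0.5, 1.5, size=task.n_ligand_atoms)
            charges[: task.n_ligand_atoms] = q  # ligand block comes first
            cs.extras["partial_charges"] = charges
            signal = sum(weights[k] * q[li] for li, k in cs.extras["contacts"])
        else:
            signal = weights[0] * c1 + weights[1] * c2
        label = float(signal + rng.normal(0.0, task.noise_sd))
        cs.label = label
        out.append((cs, label))
    return out


# -- file output -------------------------------------------------------------

def _pdb_line(i: int, atom: Atom) -> str:
    x, y, z = atom.coords
    name = f"{atom.element}{i % 100}"[:4]
    return (
        f"ATOM  {i:5d} {name:<4s} UNK A{1 + i // 100:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}\n"
    )


def _sdf_block(complex_id: str, atoms: Sequence[Atom]) -> str:
    lines = [complex_id, "  agima synthetic fixture", ""]
    lines.append(f"{len(atoms):3d}  0  0  0  0  0  0  0  0  0999 V2000")
    for a in atoms:
        x, y, z = a.coords
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def write_complex_files(cs: ComplexStructure, out_dir) -> tuple[str, str]:
    """Write the protein block as PDB and the ligand as a bond-free SDF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{cs.complex_id}_protein.pdb"
    sdf_path = out_dir / f"{cs.complex_id}_ligand.sdf"
    with open(pdb_path, "w") as fh:
        for i, atom in enumerate(cs.protein_atoms, start=1):
            fh.write(_pdb_line(i, atom))
        fh.write("END\n")
    sdf_path.write_text(_sdf_block(cs.complex_id, cs.ligand_atoms))
    return str(pdb_path), str(sdf_path)


def write_dataset(
    dataset: Sequence[tuple[ComplexStructure, float]], out_dir
) -> str:
    """Write every complex plus a complex-index TSV; returns the index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_path = out_dir / "index.tsv"
    with open(index_path, "w") as fh:
        fh.write("# complex_id\tprotein_path\tligand_path\tlabel\n")
        for cs, label in dataset:
            pdb, sdf = write_complex_files(cs, out_dir)
            fh.write(
                f"{cs.complex_id}\t{Path(pdb).name}\t{Path(sdf).name}\t{label:.6f}\n"
            )
    return str(index_path)
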