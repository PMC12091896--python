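"""Shared fixtures: tiny hand-written structure files and random sites."""

from __future__ import annotations

import numpy as np
import pytest

from agima import ComplexStructure, extract_binding_site
from agima.structures import Atom

MINIMAL_PDB = """\
ATOM      1  C   ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA A   1       1.500   0.000   0.000  1.00  0.00           N
ATOM      3  O   ALA A   1       0.000   1.400   0.000  1.00  0.00           O
END
"""

PDB_WITH_WATER = """\
ATOM      1  C   ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA A   1       1.500   0.000   0.000  1.00  0.00           N
HETATM    3  O   HOH A   2       8.000   8.000   8.000  1.00  0.00           O
ATOM      4  O   ALA A   1       0.000   1.400   0.000  1.00  0.00           O
HETATM    5  O   WAT A   3       9.000   9.000   9.000  1.00  0.00           O
END
"""

BENZENE_SDF = """\
benzene
  test fixture

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.3829    0.2211    0.0055 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5023    1.3089   -0.0018 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8792    1.0875   -0.0071 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3815   -0.2218   -0.0052 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5008   -1.3096    0.0021 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8807   -1.0882    0.0073 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  4  0
  2  3  4  0
  3  4  4  0
  4  5  4  0
  5  6  4  0
  6  1  4  0
M  END
$$$$
"""

BENZENE_MOL2 = """\
@<TRIPOS>MOLECULE
benzene
 6 6 1
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1          1.3829    0.2211    0.0055 C.ar    1  BNZ1
      2 C2          0.5023    1.3089   -0.0018 C.ar    1  BNZ1
      3 C3         -0.8792    1.0875   -0.0071 C.ar    1  BNZ1
      4 C4         -1.3815   -0.2218   -0.0052 C.ar    1  BNZ1
      5 C5         -0.5008   -1.3096    0.0021 C.ar    1  BNZ1
      6 C6          0.8807   -1.0882    0.0073 C.ar    1  BNZ1
@<TRIPOS>BOND
     1     1     2 ar
     2     2     3 ar
     3     3     4 ar
     4     4     5 ar
     5     5     6 ar
     6     6     1 ar
@<TRIPOS>SUBSTRUCTURE
     1 BNZ1        1 TEMP              0 ****  ****    0 ROOT
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "with_water.pdb"
    p.write_text(PDB_WITH_WATER)
    return p


@pytest.fixture
def benzene_sdf(tmp_path):
    p = tmp_path / "benzene.sdf"
    p.write_text(BENZENE_SDF)
    return p


@pytest.fixture
def benzene_mol2(tmp_path):
    p = tmp_path / "benzene.mol2"
    p.write_text(BENZENE_MOL2)
    return p


def random_complex(rng: np.random.Generator, n_ligand=5, n_protein=25,
                   spread=6.0) -> ComplexStructure:
    """A random point cloud split into ligand and protein blocks."""
    atoms = []
    for i in range(n_ligand):
        atoms.append(Atom("C", rng.uniform(-3, 3, 3), "ligand", i + 1))
    for j in range(n_protein):
        atoms.append(Atom("N", rng.uniform(-spread, spread, 3), "protein", j + 1))
    return ComplexStructure(complex_id=f"rand-{rng.integers(1e6)}", atoms=atoms)


def random_site(rng: np.random.Generator, n_ligand=5, n_protein=20, cutoff=100.0):
    """A binding site retaining every atom (huge cutoff) for oracle tests."""
    return extract_binding_site(random_complex(rng, n_ligand, n_protein), cutoff)


@pytest.fixture
def rng():
    return np.random.default_rng(20241007)
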