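"""Node-feature sets and chemistry perception."""

import math
import subprocess

import numpy as np
import pytest

from agima import (
    ComplexStructure,
    extract_binding_site,
    featurize,
    get_feature_set,
    load_complex,
    perceive_chemistry,
)
from agima.features import FEATURE_SETS, element_default_chemistry
from agima.structures import Atom

from conftest import MINIMAL_PDB


@pytest.fixture
def benzene_complex(tmp_path, benzene_sdf):
    pdb = tmp_path / "prot.pdb"
    pdb.write_text(MINIMAL_PDB)
    return load_complex("bz", pdb, benzene_sdf)


class TestFeatureSets:
    @pytest.mark.parametrize("name,width", [("F18", 18), ("F8", 8), ("F13", 13), ("F21", 21)])
    def test_widths(self, name, width):
        assert get_feature_set(name).m == width

    def test_f13_is_f18_minus_pharmacophoric(self):
        f18 = FEATURE_SETS["F18"].feature_names
        f13 = FEATURE_SETS["F13"].feature_names
        dropped = {"hydrophobic", "aromatic", "hb_acceptor", "hb_donor", "in_ring"}
        assert f13 == tuple(n for n in f18 if n not in dropped)

    def test_f21_extends_f18(self):
        f18 = FEATURE_SETS["F18"].feature_names
        f21 = FEATURE_SETS["F21"].feature_names
        assert f21[:18] == f18
        assert set(f21[18:]) == {"positive_charge", "negative_charge", "excluded_volume"}

    def test_unknown_set(self):
        with pytest.raises(KeyError):
            get_feature_set("F99")


class TestChemistry:
    def test_benzene_carbons(self, benzene_complex):
        chem = perceive_chemistry(benzene_complex)
        lig_chem = [c for a, c in zip(benzene_complex.atoms, chem) if a.origin == "ligand"]
        for c in lig_chem:
            assert c.aromatic and c.in_ring and c.hybridization == 2
            assert c.heavy_neighbors == 2
            assert c.hydrophobic  # ring carbon with no N/O neighbor

    def test_isolated_carbon_has_no_neighbors(self, tmp_path):
        # methane after hydrogen stripping: a single carbon
        sdf = tmp_path / "methane.sdf"
        sdf.write_text(
            "methane\n  fixture\n\n  1  0  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "M  END\n$$$$\n"
        )
        pdb = tmp_path / "prot.pdb"
        pdb.write_text(MINIMAL_PDB)
        cs = load_complex("me", pdb, sdf)
        chem = perceive_chemistry(cs)
        lig = [c for a, c in zip(cs.atoms, chem) if a.origin == "ligand"]
        assert lig[0].heavy_neighbors == 0

    def test_gasteiger_cross_implementation(self, tmp_path):
        """Charges match Open Babel's independent Gasteiger implementation."""
        from rdkit import Chem
        from rdkit.Chem import AllChem

        m = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        AllChem.EmbedMolecule(m, randomSeed=1)
        sdf = tmp_path / "ethanol.sdf"
        Chem.MolToMolFile(m, str(sdf))
        pdb = tmp_path / "prot.pdb"
        pdb.write_text(MINIMAL_PDB)
        cs = load_complex("eth", pdb, sdf, strip_hydrogens=False)
        chem = perceive_chemistry(cs)
        ours = [
            c.partial_charge for a, c in zip(cs.atoms, chem) if a.origin == "ligand"
        ]

        out = subprocess.run(
            ["obabel", str(sdf), "-omol2", "--partialcharge", "gasteiger"],
            capture_output=True, text=True, check=True,
        ).stdout
        reference = []
        in_atoms = False
        for line in out.splitlines():
            if line.startswith("@<TRIPOS>ATOM"):
                in_atoms = True
                continue
            if line.startswith("@<TRIPOS>") and in_atoms:
                break
            if in_atoms and line.strip():
                reference.append(float(line.split()[-1]))
        assert len(reference) == len(ours)
        assert max(abs(a - b) for a, b in zip(ours, reference)) < 5e-3


class TestFeaturize:
    def _simple_site(self, charges=None):
        atoms = [
            Atom("C", [0.0, 0.0, 0.0], "ligand", 1),
            Atom("N", [2.5, 0.0, 0.0], "protein", 1),
        ]
        cs = ComplexStructure("t", atoms)
        if charges is not None:
            cs.extras["partial_charges"] = charges
        site = extract_binding_site(cs, 4.0)
        return cs, site

    def test_carbon_one_hot(self):
        cs, site = self._simple_site()
        F = featurize(site, element_default_chemistry(cs), "F18")
        row = F.values[0]
        assert row[1] == 1.0  # atom_type_C
        assert row[[0, 2, 3, 4, 5, 6, 7, 8]].sum() == 0.0

    def test_one_hot_row_sums(self, rng):
        from conftest import random_complex

        cs = random_complex(rng)
        site = extract_binding_site(cs, 100.0)
        F = featurize(site, element_default_chemistry(cs), "F18")
        sums = F.values[:, :9].sum(axis=1)
        assert np.all((sums == 0) | (sums == 1))

    def test_halogen_and_metal_classes(self):
        atoms = [
            Atom("Cl", [0, 0, 0], "ligand", 1),
            Atom("Zn", [2.5, 0, 0], "protein", 1),
        ]
        cs = ComplexStructure("hm", atoms)
        site = extract_binding_site(cs, 4.0)
        F = featurize(site, element_default_chemistry(cs), "F18")
        assert F.values[0, 7] == 1.0  # halogen class
        assert F.values[1, 8] == 1.0  # metal class

    def test_f13_rows_match_f18(self):
        cs, site = self._simple_site(charges=[0.3, -0.1])
        chem = element_default_chemistry(cs)
        f18 = featurize(site, chem, "F18").values
        f13 = featurize(site, chem, "F13").values
        keep = [i for i in range(18) if i not in range(12, 17)]
        assert np.array_equal(f13, f18[:, keep])

    def test_charge_sign_split(self):
        cs, site = self._simple_site(charges=[-0.42, 0.0])
        F = featurize(site, element_default_chemistry(cs), "F8")
        names = list(F.feature_names)
        assert F.values[0, names.index("positive_charge")] == 0.0
        assert F.values[0, names.index("negative_charge")] == pytest.approx(0.42)

    def test_excluded_volume(self):
        cs, site = self._simple_site()
        chem = element_default_chemistry(cs)
        F = featurize(site, chem, "F8")
        vol = F.values[0, list(F.feature_names).index("excluded_volume")]
        assert vol == pytest.approx((4 / 3) * math.pi * chem[0].vdw_radius ** 3)

    def test_f21_first_18_equal_f18(self):
        cs, site = self._simple_site(charges=[0.2, -0.3])
        chem = element_default_chemistry(cs)
        assert np.array_equal(
            featurize(site, chem, "F21").values[:, :18],
            featurize(site, chem, "F18").values,
        )

    def test_pure_function(self):
        cs, site = self._simple_site(charges=[0.2, -0.3])
        chem = element_default_chemistry(cs)
        a = featurize(site, chem, "F21").values
        b = featurize(site, chem, "F21").values
        assert np.array_equal(a, b)

    def test_unknown_element_warns(self):
        atoms = [
            Atom("He", [0, 0, 0], "ligand", 1),  # noble gas: outside the vocabulary
            Atom("C", [2.5, 0, 0], "protein", 1),
        ]
        cs = ComplexStructure("x", atoms)
        site = extract_binding_site(cs, 4.0)
        with pytest.warns(UserWarning, match="one-hot"):
            F = featurize(site, element_default_chemistry(cs), "F18")
        assert F.values[0, :9].sum() == 0.0
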