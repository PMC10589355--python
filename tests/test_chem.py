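"""Formula arithmetic, exact masses, properties and amide enumeration."""

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from dualvs.chem import (
    ElementalFormula,
    FormulaError,
    Molecule,
    WATER,
    adduct_mass,
    compute_properties,
    enumerate_amide_products,
    monoisotopic_mass,
    parse_formula,
)
from dualvs.reference import g1_paba, sulfonamide_nucleophiles


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("H", {"H": 1}),
            ("C27H23BrN2O5S", {"C": 27, "H": 23, "Br": 1, "N": 2, "O": 5, "S": 1}),
            ("H2O", {"H": 2, "O": 1}),
            ("CH4", {"C": 1, "H": 4}),
        ],
    )
    def test_examples(self, text, expected):
        assert dict(parse_formula(text).counts) == expected

    @pytest.mark.parametrize("bad", ["", "  ", "Xx9", "C0", "C27H23q", "27C"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Cl", "Br", "P", "F"]),
            st.integers(min_value=1, max_value=60),
            min_size=1,
            max_size=6,
        )
    )
    @settings(deadline=None)
    def test_round_trip_canonical(self, counts):
        f = ElementalFormula(counts)
        assert parse_formula(f.hill()).counts == f.counts

    def test_hill_order(self):
        assert ElementalFormula({"O": 1, "C": 2, "H": 6}).hill() == "C2H6O"
        # no carbon: plain alphabetical, hydrogen not promoted
        assert ElementalFormula({"O": 1, "H": 2}).hill() == "H2O"
        assert ElementalFormula({"S": 1, "H": 2}).hill() == "H2S"


class TestMonoisotopicMass:
    def test_water(self):
        assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(
            18.0106, abs=1e-4
        )

    def test_empty_formula_is_zero(self):
        assert monoisotopic_mass(ElementalFormula({})) == 0.0

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Br"]),
            st.integers(min_value=1, max_value=40),
            max_size=5,
        ),
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Br"]),
            st.integers(min_value=1, max_value=40),
            max_size=5,
        ),
    )
    @settings(deadline=None)
    def test_additive_over_concatenation(self, a, b):
        fa, fb = ElementalFormula(a), ElementalFormula(b)
        assert monoisotopic_mass(fa + fb) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
        )

    def test_adducts_are_explicit(self):
        f = parse_formula("C6H6")
        assert adduct_mass(f, "[M+H]+") == pytest.approx(
            monoisotopic_mass(f) + 1.00728, abs=1e-4
        )
        assert adduct_mass(f, "[M-H]-") == pytest.approx(
            monoisotopic_mass(f) - 1.00728, abs=1e-4
        )
        with pytest.raises(FormulaError):
            adduct_mass(f, "[M+Na]+")


class TestProperties:
    def test_benzene_has_zero_tpsa(self):
        p = compute_properties(Molecule.from_smiles("c1ccccc1", "benzene"))
        assert p.tpsa == 0.0

    def test_ethanol_donor_acceptor_counts(self):
        p = compute_properties(Molecule.from_smiles("CCO", "ethanol"))
        assert (p.hbd, p.hba) == (1, 1)

    def test_water_molecular_weight(self):
        p = compute_properties(Molecule.from_smiles("O", "water"))
        assert p.molecular_weight == pytest.approx(18.02, abs=0.01)

    def test_invariant_to_atom_reordering(self):
        mol = Molecule.from_smiles("CC(=O)Nc1ccc(O)cc1", "paracetamol")
        n = mol.rdmol.GetNumAtoms()
        reordered = Molecule(
            "paracetamol-r",
            Chem.RenumberAtoms(mol.rdmol, list(reversed(range(n)))),
        )
        a, b = compute_properties(mol), compute_properties(reordered)
        assert a.molecular_weight == pytest.approx(b.molecular_weight, abs=1e-9)
        assert a.log_p == pytest.approx(b.log_p, abs=1e-9)
        assert (a.hbd, a.hba, a.tpsa) == (b.hbd, b.hba, b.tpsa)

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            compute_properties(Molecule("empty", Chem.Mol()))


class TestAmideEnumeration:
    def test_lead_compound_formulas(self):
        products = enumerate_amide_products(g1_paba(), sulfonamide_nucleophiles())
        formulas = {p.id.split("+")[1]: p.formula().hill() for p in products}
        assert formulas["4-methylbenzenesulfonamide"] == "C27H23BrN2O5S"
        assert formulas["4-chlorobenzenesulfonamide"] == "C26H20BrClN2O5S"

    @pytest.mark.parametrize(
        "nuc_smiles",
        ["Nc1ccccc1", "NCCO", "NS(=O)(=O)c1ccccc1", "NCc1ccc(F)cc1"],
    )
    def test_formula_conservation(self, nuc_smiles):
        acid = Molecule.from_smiles("OC(=O)c1ccccc1", "benzoic")
        nuc = Molecule.from_smiles(nuc_smiles, "nuc")
        (product,) = enumerate_amide_products(acid, [nuc])
        assert product.formula().counts == (
            acid.formula() + nuc.formula() - WATER
        ).counts

    def test_acid_without_carboxyl_is_error(self):
        with pytest.raises(ValueError, match="carboxylic"):
            enumerate_amide_products(
                Molecule.from_smiles("c1ccccc1", "benzene"),
                [Molecule.from_smiles("Nc1ccccc1", "aniline")],
            )

    def test_unreactive_nucleophile_skipped_with_warning(self):
        acid = Molecule.from_smiles("OC(=O)c1ccccc1", "benzoic")
        with pytest.warns(UserWarning, match="skipped"):
            products = enumerate_amide_products(
                acid, [Molecule.from_smiles("c1ccccc1", "benzene")]
            )
        assert products == []

    def test_multiple_sites_deterministic_order(self):
        diacid = Molecule.from_smiles("OC(=O)CCC(=O)O", "succinic")
        nuc = Molecule.from_smiles("NC", "methylamine")
        products = enumerate_amide_products(diacid, [nuc])
        assert len(products) == 2
        assert [p.id for p in products] == sorted(p.id for p in products)
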