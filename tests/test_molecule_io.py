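"""Structure/charge I/O: format round-trips, water handling, element rules."""

import numpy as np
import pytest

from eemkit import (ChargeSet, GlobuleSpec, JobTag, generate_globule,
                    read_charge_file, read_structure, read_structures,
                    strip_waters, write_charges, write_pdb)
from eemkit.errors import (ElementError, EmptyInputError, DimensionError,
                           FormatError)
from eemkit.molecule import element_from_atom_name, normalize_element


def _dummy_charges(mol, values=None):
    vals = np.asarray(values if values is not None
                      else np.linspace(-0.5, 0.5, mol.n_atoms))
    return ChargeSet(values=vals, chi_bar=None,
                     job=JobTag(method="full", parameter_set="t",
                                total_charge=0))


MOL_SINGLE_CARBON = """single carbon
  eemkit

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""

SDF_THREE_RECORDS = (
    MOL_SINGLE_CARBON + "$$$$\n"
    + MOL_SINGLE_CARBON.replace("0.0000    0.0000    0.0000 C",
                                "1.0000    0.0000    0.0000 N") + "$$$$\n"
    + MOL_SINGLE_CARBON.replace("0.0000    0.0000    0.0000 C",
                                "2.0000    0.0000    0.0000 O") + "$$$$\n")

PDB_WITH_D_AND_ALTLOC = """\
ATOM      1  N   ARG A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AARG A   1      11.639   6.071  -5.147  0.40  0.00           C
ATOM      3  CA BARG A   1      11.700   6.100  -5.200  0.60  0.00           C
ATOM      4  D1  ARG A   1      10.200   5.500  -6.600  1.00  0.00           D
ATOM      5  O   HOH B   2       2.000   2.000   2.000  1.00  0.00           O
END
"""

PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  O1  LIG A   1       1.300   0.000   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  C1  LIG A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  O1  LIG A   1       8.000   9.000   9.000  1.00  0.00           O
ENDMDL
END
"""


class TestElementRules:
    def test_two_letter_symbols_case_fixed(self):
        assert normalize_element("CL") == "Cl"
        assert normalize_element("zn") == "Zn"
        assert normalize_element("D") == "D"

    def test_unknown_symbol_raises(self):
        with pytest.raises(ElementError):
            normalize_element("Xx")

    @pytest.mark.parametrize("name,expected", [
        (" CA ", "C"),     # alpha carbon, not calcium (name starts col 2)
        ("FE1 ", "Fe"),
        ("1HB ", "H"),
        ("HO4", "H"),
        ("CL1 ", "Cl"),
    ])
    def test_pdb_name_alignment_inference(self, name, expected):
        assert element_from_atom_name(name) == expected


class TestPDB:
    def test_multi_entity_file_is_one_molecule(self, tmp_path):
        p = tmp_path / "mix.pdb"
        p.write_text(PDB_WITH_D_AND_ALTLOC)
        mol = read_structure(p)
        # N, one CA (altloc resolved), D, water O
        assert mol.n_atoms == 4
        assert mol.total_charge == 0
        assert {r.name for r in mol.residues} == {"ARG", "HOH"}

    def test_deuterium_is_a_distinct_element(self, tmp_path):
        p = tmp_path / "d.pdb"
        p.write_text(PDB_WITH_D_AND_ALTLOC)
        mol = read_structure(p)
        assert "D" in mol.element_set

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_WITH_D_AND_ALTLOC)
        mol = read_structure(p)
        ca = [a for a in mol.atoms if a.name == "CA"]
        assert len(ca) == 1
        assert ca[0].x == pytest.approx(11.700)  # the 0.60-occupancy B copy

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "nmr.pdb"
        p.write_text(PDB_TWO_MODELS)
        mol = read_structure(p)
        assert mol.n_atoms == 2
        assert mol.atoms[0].x == pytest.approx(0.0)

    def test_pdb_round_trip_of_synthetic_globule(self, tmp_path):
        mol = generate_globule(GlobuleSpec(n_atoms=80, seed=4))
        p = tmp_path / "globule.pdb"
        write_pdb(mol, p)
        back = read_structure(p)
        assert back.n_atoms == mol.n_atoms
        assert back.elements == mol.elements
        np.testing.assert_allclose(back.coordinates, mol.coordinates,
                                   atol=5e-4)  # printed to 3 decimals

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_structure(p)

    def test_unknown_extension_is_a_format_error(self, tmp_path):
        p = tmp_path / "mol.xyz"
        p.write_text("3\n")
        with pytest.raises(FormatError):
            read_structure(p)


class TestMolSdf:
    def test_single_atom_mol_file(self, tmp_path):
        p = tmp_path / "c.mol"
        p.write_text(MOL_SINGLE_CARBON)
        mol = read_structure(p)
        assert mol.n_atoms == 1
        assert mol.total_charge == 0
        assert mol.elements == ["C"]

    def test_sdf_record_count_matches_delimiters(self, tmp_path):
        p = tmp_path / "three.sdf"
        p.write_text(SDF_THREE_RECORDS)
        # independent scan for record delimiters
        n_records = SDF_THREE_RECORDS.count("$$$$")
        mols = read_structures(p)
        assert len(mols) == n_records == 3
        assert [m.elements[0] for m in mols] == ["C", "N", "O"]  # file order

    def test_read_structure_returns_first_sdf_record(self, tmp_path):
        p = tmp_path / "three.sdf"
        p.write_text(SDF_THREE_RECORDS)
        assert read_structure(p).elements == ["C"]


class TestStripWaters:
    def test_strips_all_water_names(self, water_protein_mix):
        stripped = strip_waters(water_protein_mix)
        assert stripped.n_atoms == 10
        assert [a.index for a in stripped.atoms] == list(range(10))
        assert stripped.total_charge == water_protein_mix.total_charge

    def test_idempotent(self, water_protein_mix):
        once = strip_waters(water_protein_mix)
        twice = strip_waters(once)
        assert twice.n_atoms == once.n_atoms
        assert twice.elements == once.elements

    def test_no_waters_returns_equal_molecule(self, small_globule):
        out = strip_waters(small_globule)
        assert out.n_atoms == small_globule.n_atoms
        np.testing.assert_array_equal(out.coordinates,
                                      small_globule.coordinates)

    def test_all_water_molecule_is_empty_error(self, water_protein_mix):
        waters = water_protein_mix.subset(range(10, 19))
        with pytest.raises(EmptyInputError):
            strip_waters(waters)


class TestChargeRoundTrips:
    @pytest.mark.parametrize("fmt,ext", [("mol2", "mol2"), ("pqr", "pqr"),
                                         ("tabular", "txt")])
    def test_write_read_recovers_charges(self, tmp_path, small_globule,
                                         fmt, ext):
        cs = _dummy_charges(small_globule)
        p = tmp_path / f"out.{ext}"
        write_charges(small_globule, cs, p, format=fmt)
        back = read_charge_file(p)
        np.testing.assert_allclose(back.values, cs.values, atol=5e-5)

    def test_zero_charges_round_trip(self, tmp_path, small_globule):
        cs = _dummy_charges(small_globule, np.zeros(small_globule.n_atoms))
        p = tmp_path / "zero.mol2"
        write_charges(small_globule, cs, p)
        assert np.all(read_charge_file(p).values == 0.0)

    def test_mol2_round_trip_preserves_structure(self, tmp_path,
                                                 small_globule):
        cs = _dummy_charges(small_globule)
        p = tmp_path / "s.mol2"
        write_charges(small_globule, cs, p)
        back = read_structure(p)
        assert back.n_atoms == small_globule.n_atoms
        assert back.elements == small_globule.elements
        np.testing.assert_allclose(back.coordinates,
                                   small_globule.coordinates, atol=5e-5)

    def test_pqr_preserves_given_precision(self, tmp_path, small_globule):
        vals = np.round(np.linspace(-0.9, 0.9, small_globule.n_atoms), 4)
        cs = _dummy_charges(small_globule, vals)
        p = tmp_path / "s.pqr"
        write_charges(small_globule, cs, p, format="pqr")
        np.testing.assert_array_equal(read_charge_file(p).values, vals)

    def test_length_mismatch_is_dimension_error(self, tmp_path,
                                                small_globule):
        bad = _dummy_charges(small_globule)
        bad.values = bad.values[:-1]
        with pytest.raises(DimensionError):
            write_charges(small_globule, bad, tmp_path / "x.mol2")

    def test_non_numeric_tabular_charge_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("index name chain resnum resname charge\n"
                     "0 C1 A 1 SYN 0.5\n"
                     "1 C2 A 1 SYN oops\n")
        with pytest.raises(FormatError, match="bad.txt:3"):
            read_charge_file(p)
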