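"""Atom typing rules over the FSD/SAMPL4 vocabularies.

The MOLECULES table below exercises every FSD type code that can be
reached by base typing.  The four ``*.intra`` codes are reachable only
through IHB retyping and are exercised in the IHB tests.
"""

from collections import Counter

import pytest

import solvcontact as sc
from conftest import graph_molecule, random_rotation


def multiset(mol, scheme="FSD"):
    return Counter(sc.assign_atom_types(mol, scheme).base_types)


class TestWorkedExamples:
    def test_ethanol(self, ethanol):
        got = sc.assign_atom_types(ethanol, "FSD").base_types
        assert got[:3] == ["C.3_1", "C.3_2", "O.3_1"]
        assert Counter(got) == Counter(
            {"C.3_1": 1, "C.3_2": 1, "O.3_1": 1, "H.C": 5, "H.O3": 1})

    def test_benzene(self, benzene):
        assert multiset(benzene) == Counter({"C.ar_2": 6, "H.C": 6})

    def test_acetic_acid(self, acetic_acid):
        got = sc.assign_atom_types(acetic_acid, "FSD").base_types
        assert got[:4] == ["C.3_1", "C.CO_2", "O.2", "O.es_1"]
        assert Counter(got)["H.Oa"] == 1
        assert Counter(got)["H.C"] == 3

    def test_nitromethane(self, nitromethane):
        assert multiset(nitromethane) == Counter(
            {"C.3_1": 1, "N.no2": 1, "O.no2": 2, "H.C": 3})


# --- full FSD vocabulary coverage -----------------------------------------

def ring(n, order="aromatic"):
    return [(k, (k + 1) % n, order) for k in range(n)]


MOLECULES = {
    "methane": (["C"], [], {}, {"C.3_1", "H.C"}),
    "propane": (["C", "C", "C"], [(0, 1, "single"), (1, 2, "single")], {},
                {"C.3_1", "C.3_2"}),
    "isobutane": (["C", "C", "C", "C"],
                  [(0, 1, "single"), (0, 2, "single"), (0, 3, "single")], {},
                  {"C.3_3"}),
    "neopentane": (["C", "C", "C", "C", "C"],
                   [(0, k, "single") for k in range(1, 5)], {}, {"C.3_4"}),
    "propene": (["C", "C", "C"], [(0, 1, "double"), (1, 2, "single")], {},
                {"C.2_1", "C.2_2", "C.3_1"}),
    "tetramethylethylene": (
        ["C", "C", "C", "C", "C", "C"],
        [(0, 1, "double"), (0, 2, "single"), (0, 3, "single"),
         (1, 4, "single"), (1, 5, "single")], {}, {"C.2_3"}),
    "acetylene": (["C", "C"], [(0, 1, "triple")], {}, {"C.1_1"}),
    "2-butyne": (["C", "C", "C", "C"],
                 [(0, 1, "single"), (1, 2, "triple"), (2, 3, "single")], {},
                 {"C.1_2", "C.3_1"}),
    "toluene": (["C"] * 7, ring(6) + [(0, 6, "single")], {},
                {"C.ar_2", "C.ar_3", "C.3_1"}),
    "acetaldehyde": (["C", "C", "O"], [(0, 1, "single"), (1, 2, "double")],
                     {}, {"C.CO_1", "O.2"}),
    "acetone": (["C", "C", "C", "O"],
                [(0, 1, "single"), (1, 2, "single"), (1, 3, "double")], {},
                {"C.CO_2", "O.2"}),
    "acetonitrile": (["C", "C", "N"], [(0, 1, "single"), (1, 2, "triple")],
                     {}, {"C.1_2", "N.1_1"}),
    "N-methylmethanimine": (["C", "N", "C"],
                            [(0, 1, "double"), (1, 2, "single")], {},
                            {"C.2_1", "N.2_2"}),
    "methylamine": (["C", "N"], [(0, 1, "single")], {}, {"N.3_1", "H.N3"}),
    "dimethylamine": (["C", "N", "C"], [(0, 1, "single"), (1, 2, "single")],
                      {}, {"N.3_2"}),
    "trimethylamine": (["C", "N", "C", "C"],
                       [(0, 1, "single"), (1, 2, "single"), (1, 3, "single")],
                       {}, {"N.3_3"}),
    "pyridine": (["N"] + ["C"] * 5, ring(6), {}, {"N.ar", "C.ar_2"}),
    "pyrrole": (["N"] + ["C"] * 4, ring(5), {0: 1}, {"N.ar", "H.Np"}),
    "aniline": (["C"] * 6 + ["N"], ring(6) + [(0, 6, "single")], {},
                {"N.pl_1", "C.ar_3", "H.Np"}),
    "N-methylaniline": (["C"] * 6 + ["N", "C"],
                        ring(6) + [(0, 6, "single"), (6, 7, "single")], {},
                        {"N.pl_2"}),
    "N,N-dimethylaniline": (
        ["C"] * 6 + ["N", "C", "C"],
        ring(6) + [(0, 6, "single"), (6, 7, "single"), (6, 8, "single")], {},
        {"N.pl_3"}),
    "formamide": (["C", "O", "N"], [(0, 1, "double"), (0, 2, "single")], {},
                  {"C.CO_1", "N.am_1", "H.Np"}),
    "N-methylacetamide": (["C", "C", "O", "N", "C"],
                          [(0, 1, "single"), (1, 2, "double"),
                           (1, 3, "single"), (3, 4, "single")], {},
                          {"N.am_2"}),
    "N,N-dimethylacetamide": (["C", "C", "O", "N", "C", "C"],
                              [(0, 1, "single"), (1, 2, "double"),
                               (1, 3, "single"), (3, 4, "single"),
                               (3, 5, "single")], {}, {"N.am_3"}),
    "acetic acid": (["C", "C", "O", "O"],
                    [(0, 1, "single"), (1, 2, "double"), (1, 3, "single")],
                    {}, {"C.CO_2", "O.2", "O.es_1", "H.Oa"}),
    "nitromethane": (["C", "N", "O", "O"],
                     [(0, 1, "single"), (1, 2, "double"), (1, 3, "double")],
                     {}, {"N.no2", "O.no2"}),
    "methanol": (["C", "O"], [(0, 1, "single")], {}, {"O.3_1", "H.O3"}),
    "dimethyl ether": (["C", "O", "C"], [(0, 1, "single"), (1, 2, "single")],
                       {}, {"O.3_2"}),
    "methyl acetate": (["C", "C", "O", "O", "C"],
                       [(0, 1, "single"), (1, 2, "double"), (1, 3, "single"),
                        (3, 4, "single")], {}, {"O.es_2"}),
    "dimethyl sulfone": (["C", "S", "C", "O", "O"],
                         [(0, 1, "single"), (1, 2, "single"),
                          (1, 3, "double"), (1, 4, "double")], {}, {"S.12"}),
    "methanethiol": (["C", "S"], [(0, 1, "single")], {}, {"S.3_1", "H.S"}),
    "dimethyl sulfide": (["C", "S", "C"],
                         [(0, 1, "single"), (1, 2, "single")], {}, {"S.3_2"}),
    "thioacetone": (["C", "C", "C", "S"],
                    [(0, 1, "single"), (1, 2, "single"), (1, 3, "double")],
                    {}, {"S.2"}),
    "thiophene": (["S"] + ["C"] * 4, ring(5), {}, {"S.pl"}),
    "fluoromethane": (["C", "F"], [(0, 1, "single")], {}, {"F"}),
    "chloromethane": (["C", "Cl"], [(0, 1, "single")], {}, {"Cl"}),
    "bromomethane": (["C", "Br"], [(0, 1, "single")], {}, {"Br"}),
    "iodomethane": (["C", "I"], [(0, 1, "single")], {}, {"I"}),
    "trimethyl phosphate": (
        ["P", "O", "O", "O", "O", "C", "C", "C"],
        [(0, 1, "double"), (0, 2, "single"), (0, 3, "single"),
         (0, 4, "single"), (2, 5, "single"), (3, 6, "single"),
         (4, 7, "single")], {}, {"P.10"}),
}


@pytest.mark.parametrize("name", sorted(MOLECULES))
def test_expected_codes_present(name):
    elements, bonds, h_counts, expected = MOLECULES[name]
    mol = graph_molecule(name, elements, bonds, h_counts)
    codes = set(sc.assign_atom_types(mol, "FSD").base_types)
    assert expected <= codes, f"{name}: {expected - codes} missing from {codes}"


def test_every_reachable_fsd_code_is_exercised():
    """All 48 non-intra FSD codes are realized by the fixture molecules;
    the 4 *.intra codes require retyping (covered in the IHB tests)."""
    realized = set()
    for name, (elements, bonds, h_counts, _) in MOLECULES.items():
        mol = graph_molecule(name, elements, bonds, h_counts)
        realized |= set(sc.assign_atom_types(mol, "FSD").base_types)
    fsd = set(sc.load_table("FSD").codes)
    intra = {"O.intra", "F.intra", "Cl.intra", "H.intra"}
    assert fsd - realized == intra


class TestSchemeDifferences:
    def test_sp_carbon_fails_under_sampl4(self):
        elements, bonds, h, _ = MOLECULES["acetylene"]
        mol = graph_molecule("acetylene", elements, bonds, h)
        with pytest.raises(sc.AtomTypingError) as err:
            sc.assign_atom_types(mol, "SAMPL4")
        assert "C.1" in str(err.value)

    def test_phenol_planar_oxygen_mapping(self):
        phenol = graph_molecule("phenol", ["C"] * 6 + ["O"],
                                ring(6) + [(0, 6, "single")])
        fsd = Counter(sc.assign_atom_types(phenol, "FSD").base_types)
        s4 = Counter(sc.assign_atom_types(phenol, "SAMPL4").base_types)
        assert fsd["O.3_1"] == 1 and fsd["H.O3"] == 1
        assert s4["O.pl_1"] == 1 and s4["H.Op"] == 1

    def test_anisole_aryl_ether(self):
        anisole = graph_molecule("anisole", ["C"] * 6 + ["O", "C"],
                                 ring(6) + [(0, 6, "single"), (6, 7, "single")])
        assert Counter(sc.assign_atom_types(anisole, "SAMPL4").base_types)["O.pl_2"] == 1
        assert Counter(sc.assign_atom_types(anisole, "FSD").base_types)["O.3_2"] == 1

    def test_amide_nitrogen_maps_to_planar_under_sampl4(self):
        elements, bonds, h, _ = MOLECULES["N-methylacetamide"]
        mol = graph_molecule("nma", elements, bonds, h)
        s4 = sc.assign_atom_types(mol, "SAMPL4").base_types
        assert "N.pl_2" in s4 and not any(c.startswith("N.am") for c in s4)

    @pytest.mark.parametrize("name", ["methane", "propane", "methanol",
                                      "acetone", "aniline"])
    def test_sampl4_typeable_subset_also_types_under_fsd(self, name):
        elements, bonds, h, _ = MOLECULES[name]
        mol = graph_molecule(name, elements, bonds, h)
        sc.assign_atom_types(mol, "SAMPL4")
        sc.assign_atom_types(mol, "FSD")


class TestInvariances:
    def test_rigid_transform_leaves_types_unchanged(self, rng, ethanol):
        ref = sc.assign_atom_types(ethanol, "FSD").base_types
        moved = ethanol.transformed(random_rotation(rng), rng.normal(size=3))
        assert sc.assign_atom_types(moved, "FSD").base_types == ref

    def test_atom_reordering_permutes_types(self, ethanol):
        order = list(range(ethanol.n_atoms))[::-1]
        remap = {old: new for new, old in enumerate(order)}
        atoms = [sc.make_atom(remap[a.index], a.element, a.coords)
                 for a in ethanol.atoms]
        atoms.sort(key=lambda a: a.index)
        bonds = [sc.Bond(remap[b.i], remap[b.j], b.order) for b in ethanol.bonds]
        permuted = sc.Molecule("ethanol-rev", atoms, bonds)
        ref = sc.assign_atom_types(ethanol, "FSD").base_types
        got = sc.assign_atom_types(permuted, "FSD").base_types
        assert [got[remap[i]] for i in range(len(ref))] == ref

    def test_kekulized_benzene_perceived_aromatic(self):
        kek = [(k, (k + 1) % 6, "double" if k % 2 else "single")
               for k in range(6)]
        mol = graph_molecule("benzene-kekulized", ["C"] * 6, kek)
        assert set(sc.assign_atom_types(mol, "FSD").base_types) == {"C.ar_2", "H.C"}
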