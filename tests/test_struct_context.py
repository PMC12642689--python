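"""SASA, exposure classification and atom-contact detection."""

import numpy as np
import pytest

import biotite.structure as bst

from selstruct.struct_context import (
    MAX_SASA_THEORETICAL,
    StructureModel,
    classify,
    contact_residues,
    read_structure,
    relative_sesa,
    sasa,
    vdw_contacts,
    write_structure,
)
from selstruct.synthetic_data import ToyStructureSpec, generate_toy_structure


def _carbon_atoms(coords, chain="A", res_ids=None, b=90.0):
    coords = np.asarray(coords, float)
    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = coords
    arr.chain_id[:] = chain
    arr.res_id[:] = res_ids if res_ids is not None else np.arange(1, n + 1)
    arr.res_name[:] = "ALA"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    arr.set_annotation("b_factor", np.full(n, b))
    arr.set_annotation("occupancy", np.ones(n))
    return StructureModel(arr)


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        """A lone carbon: SASA = 4*pi*(1.7+1.4)^2 = 120.76 A^2."""
        model = _carbon_atoms([[0.0, 0.0, 0.0]])
        atom_sasa, table = sasa(model)
        analytic = 4 * np.pi * 3.1**2
        assert abs(atom_sasa[0] - analytic) / analytic < 0.01
        assert np.isclose(table["sasa"].iloc[0], atom_sasa[0])

    def test_fully_caged_atom_is_zero(self):
        """An atom surrounded by an octahedral cage of overlapping atoms."""
        shell = []
        from selstruct.synthetic_data import _fibonacci_directions

        for d in _fibonacci_directions(30):
            shell.append(2.0 * d)
        model = _carbon_atoms([[0.0, 0.0, 0.0]] + shell)
        atom_sasa, _ = sasa(model)
        assert atom_sasa[0] == 0.0

    def test_separated_chains_additive(self):
        coords_a = [[0, 0, 0], [3, 0, 0]]
        coords_b = [[100, 0, 0], [103, 0, 0]]
        both = _carbon_atoms(coords_a + coords_b, res_ids=[1, 1, 2, 2])
        both.atoms.chain_id[:] = ["A", "A", "B", "B"]
        both = StructureModel(both.atoms)
        sasa_all, _ = sasa(both)
        sasa_a, _ = sasa(both, ["A"])
        sasa_b, _ = sasa(both, ["B"])
        assert np.allclose(sasa_all, np.concatenate([sasa_a, sasa_b]))

    def test_occlusion_monotone(self):
        """Adding an occluding atom never increases another atom's SASA."""
        lone, _ = sasa(_carbon_atoms([[0, 0, 0]]))
        with_neighbor, _ = sasa(_carbon_atoms([[0, 0, 0], [3.0, 0, 0]]))
        assert with_neighbor[0] < lone[0]


class TestRelativeSesa:
    def test_zero_is_buried(self):
        assert relative_sesa(0.0, "ALA") == 0.0

    def test_table_maximum_is_one(self):
        assert relative_sesa(MAX_SASA_THEORETICAL["ALA"], "ALA") == 1.0

    def test_unknown_residue_errors(self):
        with pytest.raises(KeyError):
            relative_sesa(10.0, "XYZ")

    def test_threshold_is_inclusive_at_0_3(self):
        """0.29 -> buried, 0.30 -> surface (>= boundary)."""
        max_ala = MAX_SASA_THEORETICAL["ALA"]
        # single residues far apart with tuned exposure cannot be built
        # directly; check the classification rule on the boundary instead
        from selstruct.struct_context import REL_SESA_BURIED_THRESHOLD

        assert 0.29 < REL_SESA_BURIED_THRESHOLD <= 0.30
        assert not (0.30 < REL_SESA_BURIED_THRESHOLD)


class TestStructureIO:
    def test_plddt_passthrough(self, tmp_path):
        spec = ToyStructureSpec(n_residues=6, geometry="helix",
                                plddt_track=np.array([40.0, 60, 90, 30, 50, 70]))
        model = generate_toy_structure(spec)
        path = tmp_path / "toy.pdb"
        write_structure(model, path)
        loaded = read_structure(path)
        assert np.allclose(loaded.plddt(), [40, 60, 90, 30, 50, 70])
        ctx = classify(loaded)
        # disorder strictly pLDDT < 50: 50.0 itself is structured
        assert [c.disorder for c in ctx] == [True, False, False, True, False, False]

    def test_pdb_and_mmcif_encode_same_model(self, tmp_path):
        spec = ToyStructureSpec(n_residues=5, geometry="helix")
        model = generate_toy_structure(spec)
        p_pdb = tmp_path / "m.pdb"
        p_cif = tmp_path / "m.cif"
        write_structure(model, p_pdb)
        write_structure(model, p_cif)
        a = read_structure(p_pdb)
        b = read_structure(p_cif)
        assert np.allclose(a.atoms.coord, b.atoms.coord, atol=1e-3)
        assert list(a.atoms.res_id) == list(b.atoms.res_id)
        assert list(a.atoms.element) == list(b.atoms.element)

    def test_classification_deterministic(self, tmp_path):
        from selstruct.struct_context import contexts_to_frame

        spec = ToyStructureSpec(n_residues=8, geometry="compact-cluster",
                                designed_buried=(4,))
        model = generate_toy_structure(spec)
        f1 = contexts_to_frame(classify(model))
        f2 = contexts_to_frame(classify(model))
        assert f1.equals(f2)


class TestContacts:
    def test_dimer_interface_exact(self):
        spec = ToyStructureSpec(n_residues=10, geometry="two-chain-dimer",
                                designed_interface=(3, 4, 7))
        model = generate_toy_structure(spec)
        table = contact_residues(model, (["A"], ["B"]))
        got = {(r.chain, r.residue_number) for r in table.itertuples() if r.contact}
        assert got == {(c, i) for c in "AB" for i in (3, 4, 7)}

    def test_homodimer_symmetry(self):
        spec = ToyStructureSpec(n_residues=8, geometry="two-chain-dimer",
                                designed_interface=(2, 5))
        model = generate_toy_structure(spec)
        table = contact_residues(model, (["A"], ["B"]))
        a = {r.residue_number for r in table.itertuples() if r.contact and r.chain == "A"}
        b = {r.residue_number for r in table.itertuples() if r.contact and r.chain == "B"}
        assert a == b

    def test_delta_sasa_nonnegative(self):
        spec = ToyStructureSpec(n_residues=8, geometry="two-chain-dimer",
                                designed_interface=(4,))
        model = generate_toy_structure(spec)
        table = contact_residues(model, (["A"], ["B"]))
        assert (table["delta_sasa"] >= -1e-9).all()

    def test_separated_chains_no_contacts(self):
        coords = [[0, 0, 0], [60.0, 0, 0]]
        model = _carbon_atoms(coords, res_ids=[1, 1])
        model.atoms.chain_id[:] = ["A", "B"]
        model = StructureModel(model.atoms)
        table = contact_residues(model, (["A"], ["B"]))
        assert not table["contact"].any()
        assert np.allclose(table["delta_sasa"], 0.0)

    def test_overlapping_groups_rejected(self):
        spec = ToyStructureSpec(n_residues=6, geometry="two-chain-dimer",
                                designed_interface=(3,))
        model = generate_toy_structure(spec)
        with pytest.raises(ValueError, match="overlap"):
            contact_residues(model, (["A"], ["A"]))

    def test_classify_without_complex_has_no_contacts(self):
        spec = ToyStructureSpec(n_residues=6, geometry="helix")
        model = generate_toy_structure(spec)
        ctx = classify(model)
        assert all(c.burial_category != "contact" for c in ctx)
        cats = {c.burial_category for c in ctx}
        assert cats <= {"buried", "surface"}


class TestVdwContacts:
    @pytest.mark.parametrize(
        "distance,expect_contact",
        [(3.8, True), (3.81, False), (0.0, True)],
    )
    def test_overlap_threshold_arithmetic(self, distance, expect_contact):
        """Two carbons: overlap = 1.7 + 1.7 - d >= -0.4 iff d <= 3.8."""
        model = _carbon_atoms([[0, 0, 0], [distance, 0, 0]], res_ids=[1, 2])
        contacts = vdw_contacts(model, ("A", 1), ("A", 2))
        assert bool(contacts) == expect_contact
        if contacts:
            assert np.isclose(contacts[0].overlap, 3.4 - distance)
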