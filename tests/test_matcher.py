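"""Component identification: bond perception, graph matching, renaming,
draft definitions."""

import numpy as np
import pytest

from ligannot import fixtures as fx
from ligannot.ccd import component_graph, validate_def
from ligannot.matcher import (
    MatcherError,
    build_new_definition,
    identify_component,
    match_component,
    observed_graph,
    perceive_bonds,
    rename_atoms,
    signed_volume,
)
from ligannot.structure import AtomSite, ObservedComponent

from _oracles import exhaustive_match


def _component(atoms):
    comp = ObservedComponent(comp_id="LIG", auth_chain="A", auth_seq=1, ins_code="")
    for i, (name, element, xyz) in enumerate(atoms):
        comp.atoms.append(
            AtomSite(serial=i + 1, atom_name=name, alt_loc="", comp_id="LIG",
                     auth_chain="A", auth_seq=1, ins_code="", xyz=xyz, element=element)
        )
    return comp


class TestBondPerception:
    def test_carbon_pair_bonded_at_covalent_range_only(self):
        near = _component([("C1", "C", (0, 0, 0)), ("C2", "C", (1.54, 0, 0))])
        far = _component([("C1", "C", (0, 0, 0)), ("C2", "C", (2.5, 0, 0))])
        assert perceive_bonds(near) == [(0, 1)]
        assert perceive_bonds(far) == []

    def test_single_atom_has_no_bonds(self):
        assert perceive_bonds(_component([("C1", "C", (0, 0, 0))])) == []

    def test_empty_component_is_an_error(self):
        with pytest.raises(MatcherError):
            perceive_bonds(_component([]))

    def test_unknown_element_is_named_in_the_error(self):
        comp = _component([("Q1", "Qq", (0, 0, 0))])
        with pytest.raises(MatcherError, match="Qq"):
            perceive_bonds(comp)

    @pytest.mark.parametrize("kind", ["GLC", "ALA", "BNZ"])
    def test_ideal_geometry_reproduces_the_dictionary_bond_list(self, kind):
        cdef = fx.make_ccd_fixture(kind)
        obs = fx.observed_from_def(cdef, include_hydrogens=True)
        names = [a.atom_name for a in obs.atoms]
        perceived = {frozenset((names[i], names[j])) for i, j in perceive_bonds(obs)}
        expected = {frozenset((b.atom_id_1, b.atom_id_2)) for b in cdef.bonds}
        assert perceived == expected

    def test_mismatched_altlocs_do_not_bond(self):
        comp = _component([("C1", "C", (0, 0, 0)), ("C2", "C", (1.5, 0, 0))])
        comp.atoms[0].alt_loc = "A"
        comp.atoms[1].alt_loc = "B"
        assert perceive_bonds(comp) == []


class TestMatching:
    def test_permuted_copy_matches_bijectively_with_zero_rmsd(self, glc, rng):
        obs = fx.observed_from_def(glc)
        rng.shuffle(obs.atoms)
        m = match_component(obs, glc)
        assert m is not None
        assert all(obs.atoms[i].atom_name == aid for i, aid in m.atom_map.items())
        assert m.rmsd_after_fit == pytest.approx(0.0, abs=1e-6)

    def test_glucose_without_anomeric_oxygen_still_identified(self, glc):
        obs = fx.observed_from_def(glc, drop_atoms=("O1",))
        m = match_component(obs, glc)
        assert m is not None
        assert m.missing_atoms["O1"] == "leaving"
        assert m.exact  # a leaving-atom deficit does not bar identification

    @pytest.mark.parametrize("kind", ["GLC", "ALA", "BNZ", "HOH"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_and_permutation_invariance(self, kind, seed):
        cdef = fx.make_ccd_fixture(kind)
        rng = np.random.default_rng(seed)
        rot = fx._random_rotation(rng)
        leaving = tuple(a.atom_id for a in cdef.atoms if a.leaving)
        obs = fx.observed_from_def(cdef, drop_atoms=leaving, rotation=rot,
                                   translation=rng.uniform(-20, 20, 3))
        rng.shuffle(obs.atoms)
        m = match_component(obs, cdef)
        assert m is not None
        assert all(obs.atoms[i].atom_name == aid for i, aid in m.atom_map.items())

    @pytest.mark.parametrize("kind", ["ALA", "BNZ", "HOH"])
    def test_agrees_with_exhaustive_enumeration_oracle(self, kind):
        cdef = fx.make_ccd_fixture(kind)
        rng = np.random.default_rng(7)
        obs = fx.observed_from_def(cdef, rotation=fx._random_rotation(rng))
        rng.shuffle(obs.atoms)
        solutions = exhaustive_match(obs, cdef)
        m = match_component(obs, cdef)
        assert m is not None
        assert m.atom_map in solutions
        # the true (name-preserving) assignment is among the oracle's solutions
        truth = {i: a.atom_name for i, a in enumerate(obs.atoms) if not a.is_hydrogen}
        assert truth in solutions

    def test_zero_heavy_atom_component_does_not_match(self, glc):
        comp = _component([("H1", "H", (0, 0, 0))])
        assert match_component(comp, glc) is None

    def test_identification_ranks_the_formula_compatible_candidate_first(
        self, glc, dictionary
    ):
        obs = fx.observed_from_def(glc, drop_atoms=("O1",))
        ranked = identify_component(obs, dictionary)
        assert ranked and ranked[0].comp_id == "GLC"

    def test_water_identified_as_water(self, hoh, dictionary):
        obs = fx.observed_from_def(hoh)
        assert identify_component(obs, dictionary)[0].comp_id == "HOH"

    def test_novel_molecule_yields_no_candidates(self, dictionary):
        # a phosphorus-bearing fragment matches nothing in the fixture dictionary
        comp = _component([("P1", "P", (0, 0, 0)), ("O1", "O", (1.5, 0, 0))])
        assert identify_component(comp, dictionary) == []


class TestRenaming:
    def test_renaming_applies_dictionary_nomenclature(self, glc, rng):
        obs = fx.observed_from_def(glc)
        for a in obs.atoms:
            a.atom_name = "X" + a.atom_name  # scramble deposition names
        m = match_component(obs, glc)
        renamed = rename_atoms(obs, m)
        dict_names = {a.atom_id for a in glc.heavy_atoms()}
        assert {a.atom_name for a in renamed.atoms} <= dict_names
        assert [a.xyz for a in renamed.atoms] == [a.xyz for a in obs.atoms]

    def test_renaming_then_rematching_is_the_identity(self, glc, rng):
        obs = fx.observed_from_def(glc)
        rng.shuffle(obs.atoms)
        renamed = rename_atoms(obs, match_component(obs, glc))
        m2 = match_component(renamed, glc)
        assert all(renamed.atoms[i].atom_name == aid for i, aid in m2.atom_map.items())

    def test_map_to_absent_atom_is_an_error(self, glc):
        obs = fx.observed_from_def(glc)
        m = match_component(obs, glc)
        m.atom_map[999] = "C1"
        with pytest.raises(MatcherError):
            rename_atoms(obs, m)


class TestDraftDefinitions:
    def test_two_carbon_fragment_drafts_a_single_bond(self):
        comp = _component([("C1", "C", (0, 0, 0)), ("C2", "C", (1.54, 0, 0))])
        draft = build_new_definition(comp, "ET1")
        assert draft.formula == "C2"
        assert [(b.atom_id_1, b.atom_id_2, b.order) for b in draft.bonds] == [
            ("C1", "C2", "SING")
        ]

    def test_draft_passes_dictionary_validation(self, ala):
        obs = fx.observed_from_def(ala, drop_atoms=("OXT",))
        draft = build_new_definition(obs, "NW1")
        assert validate_def(draft) == []
        assert draft.release_status == "draft"

    def test_duplicate_proposed_id_is_rejected(self, dictionary):
        comp = _component([("C1", "C", (0, 0, 0))])
        with pytest.raises(MatcherError):
            build_new_definition(comp, "GLC", dictionary)

    def test_alpha_carbon_handedness_follows_the_signed_volume_oracle(self, ala):
        obs = fx.observed_from_def(ala, include_hydrogens=True)
        draft = build_new_definition(obs, "NW2")
        pos = {a.atom_name: np.asarray(a.xyz) for a in obs.atoms}
        nbrs = sorted(["N", "C", "CB", "HA"])[:3]
        vol = signed_volume(pos["CA"], np.array([pos[n] for n in nbrs]))
        expected = "R" if vol > 0 else "S"
        assert draft.atom("CA").stereo_config == expected

    def test_mirror_image_flips_the_drafted_handedness(self, ala):
        obs = fx.observed_from_def(ala, include_hydrogens=True)
        stereo1 = build_new_definition(obs, "NW3").atom("CA").stereo_config
        for a in obs.atoms:
            a.xyz = (-a.xyz[0], a.xyz[1], a.xyz[2])
        stereo2 = build_new_definition(obs, "NW4").atom("CA").stereo_config
        assert {stereo1, stereo2} == {"R", "S"}

    def test_planar_carbon_ring_is_drafted_aromatic(self, bnz):
        obs = fx.observed_from_def(bnz)
        draft = build_new_definition(obs, "AR1")
        ring_orders = {b.order for b in draft.bonds}
        assert ring_orders == {"AROM"}
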