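"""Covalent linkages, metal coordination spheres, REMARK 620 and
_pdbx_struct_conn_angle round trips."""

import math

import numpy as np
import pytest

from ligannot import fixtures as fx
from ligannot.linkages import (
    LinkageError,
    coordination_center,
    detect_linkages,
    find_metal_sites,
    parse_conn_angle,
    parse_remark620,
    write_conn_angle,
    write_remark620,
    write_struct_conn,
)
from ligannot.structure import AtomSite, CrystalCell, ObservedComponent, StructureModel

TETRA_ANGLE = math.degrees(math.acos(-1.0 / 3.0))


def _model_from(components, cell_edge=60.0):
    cell = CrystalCell(cell_edge, cell_edge, cell_edge, 90, 90, 90, space_group="P 1")
    model = StructureModel(cell=cell)
    for comp in components:
        model.components.append(comp)
        model.atom_sites.extend(comp.atoms)
    return model


def _residue(comp_id, chain, seq, atoms, polymer=False):
    comp = ObservedComponent(comp_id=comp_id, auth_chain=chain, auth_seq=seq,
                             ins_code="", is_polymer_residue=polymer)
    for i, (name, element, xyz) in enumerate(atoms):
        comp.atoms.append(AtomSite(serial=seq * 100 + i, atom_name=name, alt_loc="",
                                   comp_id=comp_id, auth_chain=chain, auth_seq=seq,
                                   ins_code="", xyz=xyz, element=element))
    return comp


class TestLinkageDetection:
    def test_glycosidic_oxygen_carbon_pair_is_covalent(self):
        a = _residue("GLC", "C", 1, [("O4", "O", (0.0, 0.0, 0.0))])
        b = _residue("GLC", "C", 2, [("C1", "C", (1.42, 0.0, 0.0))])
        links = detect_linkages(_model_from([a, b]))
        assert len(links) == 1
        assert links[0].kind == "covale"
        assert {links[0].partner1.atom_name, links[0].partner2.atom_name} == {"O4", "C1"}

    def test_lone_component_has_no_linkages(self):
        glc = fx.make_ccd_fixture("GLC")
        comp = fx.observed_from_def(glc, translation=(30, 30, 30))
        assert detect_linkages(_model_from([comp])) == []

    def test_cyclodextrin_ring_has_exactly_seven_intersugar_links(self):
        model, truth, _ = fx.cyclodextrin_scene(0)
        links = [l for l in detect_linkages(model)
                 if l.partner1.comp_id == "GLC" and l.partner2.comp_id == "GLC"]
        assert len(links) == len(truth.links) == 7
        for l in links:
            assert l.kind == "covale"
            assert {l.partner1.atom_name, l.partner2.atom_name} == {"O4", "C1"}
            assert l.distance == pytest.approx(1.42, abs=0.01)

    def test_peptide_backbone_bonds_are_not_reported(self):
        model, _ = fx.peptide_chain_scene(5)
        assert detect_linkages(model) == []

    def test_cysteine_sulfur_pair_is_a_disulfide(self):
        a = _residue("CYS", "A", 10, [("SG", "S", (0, 0, 0))], polymer=True)
        b = _residue("CYS", "A", 40, [("SG", "S", (2.05, 0, 0))], polymer=True)
        links = detect_linkages(_model_from([a, b]))
        assert [l.kind for l in links] == ["disulf"]

    def test_metal_donor_pair_is_metalc_and_matches_the_coordination_sphere(self):
        model, _ = fx.metal_scene("tetrahedral")
        links = detect_linkages(model)
        metalc = [l for l in links if l.kind == "metalc"]
        center = coordination_center(model, find_metal_sites(model)[0])
        assert len(metalc) == len(center.ligators) == 4
        link_partners = {
            (l.partner1.atom_name if l.partner1.comp_id == "GLU" else l.partner2.atom_name,
             l.partner1.auth_seq if l.partner1.comp_id == "GLU" else l.partner2.auth_seq)
            for l in metalc
        }
        lig_partners = {(l.atom.atom_name, l.atom.auth_seq) for l in center.ligators}
        assert link_partners == lig_partners

    def test_struct_conn_category_row_count(self):
        model, _, _ = fx.cyclodextrin_scene(0)
        links = detect_linkages(model)
        text = write_struct_conn(links)
        import gemmi

        cat = gemmi.cif.read_string(text)[0].get_mmcif_category("_struct_conn.")
        assert len(cat["id"]) == len(links)


class TestCoordination:
    def test_tetrahedral_center_has_six_ideal_angles(self):
        model, truth = fx.metal_scene("tetrahedral")
        center = coordination_center(model, find_metal_sites(model)[0])
        assert len(center.ligators) == 4
        assert len(center.angles) == 6  # k(k-1)/2
        for _, _, ang in center.angles:
            assert ang == pytest.approx(TETRA_ANGLE, abs=1e-6)

    def test_collinear_ligators_subtend_180_degrees(self):
        model, _ = fx.metal_scene("linear")
        center = coordination_center(model, find_metal_sites(model)[0])
        assert len(center.angles) == 1
        assert center.angles[0][2] == pytest.approx(180.0, abs=1e-6)

    def test_angles_are_invariant_under_rigid_motion(self, rng):
        model, _ = fx.metal_scene("tetrahedral")
        ref = sorted(a for _, _, a in
                     coordination_center(model, find_metal_sites(model)[0]).angles)
        rot = fx._random_rotation(rng)
        shift = rng.uniform(-5, 5, 3)
        for atom in model.atom_sites:
            atom.xyz = tuple(rot @ np.asarray(atom.xyz) + shift)
        moved = sorted(a for _, _, a in
                       coordination_center(model, find_metal_sites(model)[0]).angles)
        assert moved == pytest.approx(ref, abs=1e-6)

    def test_alternate_conformers_are_separate_ligators(self):
        zn = _residue("ZN", "A", 500, [("ZN", "Zn", (0, 0, 0))])
        glu = ObservedComponent(comp_id="GLU", auth_chain="B", auth_seq=1, ins_code="",
                                is_polymer_residue=True)
        for alt, y in (("A", 2.1), ("B", -2.1)):
            glu.atoms.append(AtomSite(serial=len(glu.atoms) + 2, atom_name="OE1",
                                      alt_loc=alt, comp_id="GLU", auth_chain="B",
                                      auth_seq=1, ins_code="", xyz=(0.0, y, 0.0),
                                      element="O"))
        model = _model_from([zn, glu])
        center = coordination_center(model, zn.atoms[0])
        assert len(center.ligators) == 2  # one per conformer
        assert {l.atom.alt_loc for l in center.ligators} == {"A", "B"}
        assert center.angles[0][2] == pytest.approx(180.0, abs=1e-6)

    def test_unsupported_metal_is_an_error(self):
        model, _ = fx.metal_scene("tetrahedral")
        fake = model.atom_sites[0]
        fake.element = "C"
        with pytest.raises(LinkageError):
            coordination_center(model, fake)


class TestSerialization:
    def test_four_ligator_center_writes_six_angle_rows(self):
        model, _ = fx.metal_scene("tetrahedral")
        center = coordination_center(model, find_metal_sites(model)[0])
        rows = parse_conn_angle(write_conn_angle([center]))
        assert len(rows) == 6

    def test_zero_ligator_center_writes_header_only(self):
        model, _ = fx.metal_scene("tetrahedral")
        center = coordination_center(model, find_metal_sites(model)[0])
        center.ligators, center.angles = [], []
        text = write_remark620([center])
        assert "ZN" in text
        assert parse_remark620(text)[0].angles == []
        assert parse_conn_angle(write_conn_angle([center])) == []

    def test_remark620_round_trips_angles_to_tenth_of_a_degree(self):
        model, _ = fx.metal_scene("tetrahedral")
        center = coordination_center(model, find_metal_sites(model)[0])
        (back,) = parse_remark620(write_remark620([center]))
        assert len(back.ligators) == 4
        got = {(i, j): a for i, j, a in back.angles}
        for i, j, a in center.angles:
            assert got[(i, j)] == pytest.approx(a, abs=0.05)

    def test_conn_angle_category_round_trips_the_same_numbers(self):
        model, _ = fx.metal_scene("tetrahedral")
        center = coordination_center(model, find_metal_sites(model)[0])
        rows = parse_conn_angle(write_conn_angle([center]))
        for (lig1, metal, lig2, value), (i, j, ang) in zip(rows, center.angles):
            assert metal.comp_id == "ZN"
            assert value == pytest.approx(ang, abs=0.05)
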