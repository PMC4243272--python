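"""Geometry validation against ideal coordinates and the LLDF Z-score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligannot import fixtures as fx
from ligannot.matcher import match_component
from ligannot.sites import SiteParams, delineate_sites
from ligannot.validation import (
    RsrTable,
    ValidationError,
    geometry_check,
    lldf,
)


def _matched(cdef, **kwargs):
    obs = fx.observed_from_def(cdef, **kwargs)
    return obs, match_component(obs, cdef)


class TestGeometry:
    def test_ideal_coordinates_have_zero_deviations(self, glc):
        obs, m = _matched(glc)
        report = geometry_check(obs, m, glc)
        assert report.bond_deviations
        assert all(abs(d) < 1e-9 for d in report.bond_deviations.values())
        assert all(abs(d) < 1e-7 for d in report.angle_deviations.values())
        assert report.chirality_flips == []

    def test_single_stretched_bond_is_flagged_with_its_magnitude(self, glc):
        obs, m = _matched(glc)
        # stretch C6-O6 by +0.3 A along the bond, displacing only O6
        pos = {a.atom_name: np.asarray(a.xyz) for a in obs.atoms}
        direction = (pos["O6"] - pos["C6"]) / np.linalg.norm(pos["O6"] - pos["C6"])
        for a in obs.atoms:
            if a.atom_name == "O6":
                a.xyz = tuple(pos["O6"] + 0.3 * direction)
        report = geometry_check(obs, m, glc)
        stretched = {k: v for k, v in report.bond_deviations.items() if abs(v) > 1e-6}
        assert set(stretched) == {("C6", "O6")}
        assert stretched[("C6", "O6")] == pytest.approx(0.300, abs=1e-6)

    def test_mirror_image_flips_every_assigned_stereocenter(self, ala):
        # give the definition an assigned stereocenter first
        from dataclasses import replace
        ala2 = replace(ala, atoms=[
            replace(a, stereo_config="S" if a.atom_id == "CA" else a.stereo_config)
            for a in ala.atoms
        ])
        obs = fx.observed_from_def(ala2)
        for a in obs.atoms:
            a.xyz = (-a.xyz[0], a.xyz[1], a.xyz[2])
        m = match_component(obs, ala2)
        report = geometry_check(obs, m, ala2)
        assert report.chirality_flips == ["CA"]

    def test_rigid_transform_of_ideal_geometry_keeps_deviations_zero(self, glc, rng):
        rot = fx._random_rotation(rng)
        obs, m = _matched(glc, rotation=rot, translation=(4.0, -2.0, 9.0))
        report = geometry_check(obs, m, glc)
        assert all(abs(d) < 1e-6 for d in report.bond_deviations.values())
        assert report.chirality_flips == []

    def test_definition_without_ideal_coordinates_reports_a_notice(self, glc):
        from dataclasses import replace
        bare = replace(glc, atoms=[replace(a, ideal_xyz=None) for a in glc.atoms])
        obs = fx.observed_from_def(glc)
        m = match_component(obs, bare)
        report = geometry_check(obs, m, bare)
        assert not report.ideal_available
        assert report.bond_deviations == {}
        assert report.notice


def _rsr_text(rows):
    lines = ["chain\tseq\tins\tcomp_id\trsr"]
    lines += [f"{c}\t{s}\t.\t{r}\t{v}" for c, s, r, v in rows]
    return "\n".join(lines) + "\n"


class TestLldf:
    def _scene(self):
        return fx.placed_contact_scene(close=(3.0, 3.2, 3.4), far=())

    def test_hand_computed_fixture_scores_ten_and_is_flagged(self):
        model, _ = self._scene()
        rows = [("B", 1, "ALA", 0.10), ("B", 2, "ALA", 0.12), ("B", 3, "ALA", 0.14),
                ("A", 301, "BNZ", 0.32)]
        table = RsrTable.from_tsv(_rsr_text(rows))
        result = lldf(model, table, model.ligands()[0])
        # sample sd of {0.10, 0.12, 0.14} is exactly 0.02
        assert result.sd_rsr == pytest.approx(0.02)
        assert result.lldf == pytest.approx(10.0)
        assert result.flagged

    def test_ligand_at_the_neighbor_mean_scores_zero(self):
        model, _ = self._scene()
        rows = [("B", 1, "ALA", 0.10), ("B", 2, "ALA", 0.12), ("B", 3, "ALA", 0.14),
                ("A", 301, "BNZ", 0.12)]
        result = lldf(model, RsrTable.from_tsv(_rsr_text(rows)), model.ligands()[0])
        assert result.lldf == pytest.approx(0.0)
        assert not result.flagged

    def test_flag_threshold_is_strictly_greater_than_two(self):
        model, _ = self._scene()

        def score(lig_rsr):
            rows = [("B", 1, "ALA", 0.10), ("B", 2, "ALA", 0.12),
                    ("B", 3, "ALA", 0.14), ("A", 301, "BNZ", lig_rsr)]
            return lldf(model, RsrTable.from_tsv(_rsr_text(rows)), model.ligands()[0])

        assert score(0.12 + 2.5 * 0.02).flagged
        assert not score(0.12 + 2.0 * 0.02).flagged

    @given(shift=st.floats(-0.5, 0.5), scale=st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_z_score_is_invariant_under_shared_shift_and_scale(self, shift, scale):
        model, _ = fx.placed_contact_scene(close=(3.0, 3.2, 3.4), far=())
        base = [0.08, 0.11, 0.15, 0.31]
        transformed = [scale * v + shift + 1.0 for v in base]  # keep values positive
        rows_a = [("B", 1, "ALA", base[0]), ("B", 2, "ALA", base[1]),
                  ("B", 3, "ALA", base[2]), ("A", 301, "BNZ", base[3])]
        rows_b = [("B", 1, "ALA", transformed[0]), ("B", 2, "ALA", transformed[1]),
                  ("B", 3, "ALA", transformed[2]), ("A", 301, "BNZ", transformed[3])]
        lig = model.ligands()[0]
        za = lldf(model, RsrTable.from_tsv(_rsr_text(rows_a)), lig).lldf
        zb = lldf(model, RsrTable.from_tsv(_rsr_text(rows_b)), lig).lldf
        assert za == pytest.approx(zb, abs=1e-9)

    def test_residue_outside_the_cutoff_does_not_change_the_score(self):
        near_only, _ = fx.placed_contact_scene(close=(3.0, 3.2, 3.4), far=())
        with_far, _ = fx.placed_contact_scene(close=(3.0, 3.2, 3.4), far=(8.0,))
        rows = [("B", 1, "ALA", 0.10), ("B", 2, "ALA", 0.12), ("B", 3, "ALA", 0.14),
                ("B", 4, "ALA", 0.55), ("A", 301, "BNZ", 0.32)]
        table = RsrTable.from_tsv(_rsr_text(rows))
        za = lldf(near_only, table, near_only.ligands()[0])
        zb = lldf(with_far, table, with_far.ligands()[0])
        assert zb.n_neighbors == 3  # the 8 A residue is not selected
        assert zb.lldf == pytest.approx(za.lldf)

    def test_neighbor_selection_agrees_with_the_site_engine_at_five_angstroms(self):
        model, _ = fx.placed_contact_scene(close=(3.0, 3.6, 4.4, 4.9), far=(5.5, 7.0))
        rows = [("B", i, "ALA", 0.10 + 0.01 * i) for i in range(1, 7)]
        rows.append(("A", 301, "BNZ", 0.30))
        result = lldf(model, RsrTable.from_tsv(_rsr_text(rows)), model.ligands()[0])
        (site,) = delineate_sites(model, SiteParams(cutoff=5.0,
                                                    include_waters_as_neighbors=False))
        assert set(result.neighbors) == {c.residue for c in site.contacts}

    def test_fewer_than_two_neighbors_is_an_error(self):
        model, _ = fx.placed_contact_scene(close=(3.0,), far=())
        rows = [("B", 1, "ALA", 0.10), ("A", 301, "BNZ", 0.30)]
        with pytest.raises(ValidationError, match="standard deviation"):
            lldf(model, RsrTable.from_tsv(_rsr_text(rows)), model.ligands()[0])

    def test_ligand_missing_from_the_table_is_an_error(self):
        model, _ = self._scene()
        rows = [("B", 1, "ALA", 0.10), ("B", 2, "ALA", 0.12), ("B", 3, "ALA", 0.14)]
        with pytest.raises(ValidationError, match="missing"):
            lldf(model, RsrTable.from_tsv(_rsr_text(rows)), model.ligands()[0])

    def test_degenerate_equal_neighbors_is_an_error(self):
        model, _ = self._scene()
        rows = [("B", 1, "ALA", 0.12), ("B", 2, "ALA", 0.12), ("B", 3, "ALA", 0.12),
                ("A", 301, "BNZ", 0.30)]
        with pytest.raises(ValidationError, match="zero"):
            lldf(model, RsrTable.from_tsv(_rsr_text(rows)), model.ligands()[0])

    def test_generated_table_recovers_the_designed_offset(self):
        model, _ = fx.placed_contact_scene(
            close=(2.8, 3.0, 3.2, 3.4, 3.6, 4.0, 4.4, 4.8), far=(6.5,)
        )
        vals = []
        for seed in range(40):
            table, expected = fx.make_rsr_fixture(
                model, ligand_offset=0.06, noise_sigma=0.02, seed=seed
            )
            vals.append(lldf(model, table, model.ligands()[0]).lldf)
        assert expected == pytest.approx(3.0)
        assert np.mean(vals) == pytest.approx(3.0, abs=0.6)

    def test_rsr_table_round_trips_through_tsv(self):
        model, _ = self._scene()
        table, _ = fx.make_rsr_fixture(model, seed=3)
        back = RsrTable.from_tsv(table.to_tsv())
        assert len(back) == len(table)
        for key, val in table._index.items():
            assert back.get(key) == pytest.approx(val)
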