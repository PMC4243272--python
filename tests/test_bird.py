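"""Peptide-like representation rules and PRD/FAM reference files."""

import pytest

from ligannot import fixtures as fx
from ligannot.bird import (
    GROUP,
    NONPOLYMER_SUBCOMPONENTS,
    POLYMER,
    BirdError,
    PrdChain,
    PrdEntry,
    PrdFamily,
    classify_peptide_like,
    detect_peptide_bonds,
    max_consecutive_peptide_bonds,
    parse_fam,
    parse_prd,
    validate_family,
    write_fam,
    write_prd,
)


class TestPeptideBondDetection:
    def test_dipeptide_has_one_peptide_bond(self):
        mol = fx.make_peptide_molecule(2)
        bonds = detect_peptide_bonds(mol)
        assert len(bonds) == 1
        assert (bonds[0].c_key, bonds[0].n_key) == ("A1", "A2")

    def test_ester_junction_is_not_a_peptide_bond(self):
        mol = fx.make_peptide_molecule(2, ester_junctions=[0])
        assert detect_peptide_bonds(mol) == []

    def test_seven_residue_core_has_six_peptide_bonds(self):
        mol = fx.make_peptide_molecule(7)
        assert len(detect_peptide_bonds(mol)) == 6


class TestConsecutiveCount:
    def test_tripeptide_counts_two(self):
        mol = fx.make_peptide_molecule(3)
        assert max_consecutive_peptide_bonds(detect_peptide_bonds(mol), mol) == 2

    def test_warhead_capped_single_residue_counts_at_most_one(self):
        mol = fx.make_peptide_molecule(1, warhead=True)
        assert max_consecutive_peptide_bonds(detect_peptide_bonds(mol), mol) <= 1

    def test_branch_point_contributes_its_longest_branch(self):
        # main chain of 3 with a 3-residue branch on the middle residue
        mol = fx.make_peptide_molecule(3, branch_at=2, branch_length=3)
        bonds = detect_peptide_bonds(mol)
        # exhaustive path-search oracle over the directed bond graph
        edges = {(b.c_key, b.n_key) for b in bonds}

        def longest_from(node, used):
            best = 0
            for c, n in edges:
                for a, b in ((c, n), (n, c)):
                    if a == node and (a, b) not in used and (b, a) not in used:
                        best = max(best, 1 + longest_from(b, used | {(a, b)}))
            return best

        oracle = max(longest_from(k, frozenset()) for k in
                     {k for e in edges for k in e})
        assert max_consecutive_peptide_bonds(bonds, mol) == oracle == 4


TRUTH_TABLE = []
# linear peptides: POLYMER iff at least two consecutive bonds (k >= 3)
for k in range(1, 9):
    TRUTH_TABLE.append(
        (f"linear-{k}", dict(k=k), POLYMER if k >= 3 else NONPOLYMER_SUBCOMPONENTS)
    )
# cyclic peptides of length >= 3 always reach two consecutive bonds
for k in (3, 4, 5, 6):
    TRUTH_TABLE.append((f"cyclic-{k}", dict(k=k, cyclic=True), POLYMER))
# ester junctions break the peptide run
TRUTH_TABLE += [
    ("depsi-2", dict(k=2, ester_junctions=[0]), NONPOLYMER_SUBCOMPONENTS),
    ("depsi-3", dict(k=3, ester_junctions=[1]), NONPOLYMER_SUBCOMPONENTS),
    ("depsi-4-mid", dict(k=4, ester_junctions=[1]), NONPOLYMER_SUBCOMPONENTS),
    ("depsi-5-late", dict(k=5, ester_junctions=[3]), POLYMER),
    ("depsi-5-both", dict(k=5, ester_junctions=[1, 3]), NONPOLYMER_SUBCOMPONENTS),
]
# warhead-capped inhibitors stay non-polymeric until the peptide run suffices
TRUTH_TABLE += [
    ("warhead-1", dict(k=1, warhead=True), NONPOLYMER_SUBCOMPONENTS),
    ("warhead-2", dict(k=2, warhead=True), NONPOLYMER_SUBCOMPONENTS),
    ("warhead-3", dict(k=3, warhead=True), POLYMER),
]
# sugar and acyl attachments force the group representation
for k in (2, 3, 5, 7):
    TRUTH_TABLE.append((f"glyco-{k}", dict(k=k, n_sugars=1), GROUP))
TRUTH_TABLE += [
    ("glyco-7-3sugars", dict(k=7, n_sugars=3), GROUP),
    ("lipo-2", dict(k=2, acyl=True), GROUP),
    ("lipo-5", dict(k=5, acyl=True), GROUP),
    ("lipoglyco-7", dict(k=7, n_sugars=3, acyl=True), GROUP),
]
# branched cores
TRUTH_TABLE += [
    ("branched-2+1", dict(k=2, branch_at=1, branch_length=1), POLYMER),
    ("branched-3+2", dict(k=3, branch_at=2, branch_length=2), POLYMER),
    ("branched-1+1", dict(k=1, branch_at=1, branch_length=1), NONPOLYMER_SUBCOMPONENTS),
]
assert len(TRUTH_TABLE) >= 30


class TestClassification:
    @pytest.mark.parametrize("name,kwargs,expected",
                             TRUTH_TABLE, ids=[t[0] for t in TRUTH_TABLE])
    def test_constructed_truth_table(self, name, kwargs, expected):
        cls = classify_peptide_like(fx.make_peptide_molecule(**kwargs))
        assert cls.category == expected

    def test_polymer_threshold_matches_the_bond_count(self):
        for k in range(1, 8):
            cls = classify_peptide_like(fx.make_peptide_molecule(k))
            assert cls.max_consecutive_peptide_bonds == max(0, k - 1)
            assert (cls.category == POLYMER) == (k >= 3)

    def test_dipeptide_sequence_runs_amino_to_carboxy(self):
        mol = fx.make_peptide_molecule(2)
        cls = classify_peptide_like(mol)
        assert cls.category == NONPOLYMER_SUBCOMPONENTS
        assert cls.subcomponent_sequence == ["ALA", "ALA"]
        bonds = detect_peptide_bonds(mol)
        assert bonds[0].c_key == "A1"  # A1 donates the carbonyl: A1 is N-terminal

    def test_group_lists_its_attachments(self):
        cls = classify_peptide_like(fx.make_peptide_molecule(7, n_sugars=3, acyl=True))
        assert cls.category == GROUP
        assert set(cls.nonpeptide_attachments) == {"GLC", "FAT"}

    def test_classification_ignores_subcomponent_key_naming(self):
        mol = fx.make_peptide_molecule(4, n_sugars=1)
        ref = classify_peptide_like(mol)
        for i, sub in enumerate(mol.subcomponents):
            old = sub.key
            sub.key = f"Z{i}"
            for link in mol.links:
                if link.key1 == old:
                    link.key1 = sub.key
                if link.key2 == old:
                    link.key2 = sub.key
        renamed = classify_peptide_like(mol)
        assert renamed.category == ref.category
        assert renamed.max_consecutive_peptide_bonds == ref.max_consecutive_peptide_bonds


class TestPrdFam:
    def _entry(self):
        return PrdEntry(
            prd_id="PRD_000123",
            name="synthetic glycopeptide fixture",
            structural_class="glycopeptide",
            function="antibiotic",
            chains=[PrdChain("1", ["ALA"] * 7), PrdChain("2", ["GLC", "GLC"])],
            links=fx.make_peptide_molecule(2).links,
        )

    def test_prd_round_trip_is_identity(self):
        entry = self._entry()
        back = parse_prd(write_prd(entry))
        assert back.prd_id == entry.prd_id
        assert back.structural_class == entry.structural_class
        assert [(c.chain_id, c.comp_ids) for c in back.chains] == [
            (c.chain_id, c.comp_ids) for c in entry.chains
        ]
        assert len(back.links) == len(entry.links)

    def test_malformed_prd_id_is_rejected(self):
        with pytest.raises(BirdError):
            PrdEntry(prd_id="PRD_12")

    def test_family_round_trip_and_membership(self):
        fam = PrdFamily(
            fam_id="FAM_000010",
            name="glycopeptide antibiotics",
            member_prd_ids=["PRD_000001", "PRD_000002", "PRD_000003"],
            function="cell-wall synthesis inhibition",
        )
        back = parse_fam(write_fam(fam))
        assert back.member_prd_ids == fam.member_prd_ids
        assert back.name == fam.name

    def test_unknown_family_member_is_reported_by_name(self):
        fam = PrdFamily(fam_id="FAM_000011",
                        member_prd_ids=["PRD_000001", "PRD_999999"])
        issues = validate_family(fam, ["PRD_000001"])
        assert len(issues) == 1
        assert "PRD_999999" in issues[0].message

    def test_empty_family_is_rejected(self):
        with pytest.raises(BirdError):
            PrdFamily(fam_id="FAM_000012", member_prd_ids=[])
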