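"""Representation rules for peptide-like inhibitors and antibiotics (BIRD).

A peptide-like molecule is decomposed into its component chemical entities
(subcomponents identified against the dictionary) joined by inter-component
linkages.  The number of consecutive peptide bonds then decides the
representation: two or more make the molecule a standard polymer; fewer
make it a non-polymer with a recorded subcomponent sequence running from
the amino (N) to the carboxy (C) terminus; molecules whose peptide core
carries sugar or fatty-acid attachments are represented as a group.
Per-molecule descriptions live in PRD files, chemically related molecules
are collected into FAM families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import networkx as nx

from .ccd import ChemCompDef, Issue

__all__ = [
    "PeptideBond",
    "PeptideClassification",
    "Subcomponent",
    "SubLink",
    "PeptideLikeMolecule",
    "PrdEntry",
    "PrdFamily",
    "BirdError",
    "detect_peptide_bonds",
    "max_consecutive_peptide_bonds",
    "classify_peptide_like",
    "parse_prd",
    "write_prd",
    "parse_fam",
    "write_fam",
    "validate_family",
]

POLYMER = "POLYMER"
NONPOLYMER_SUBCOMPONENTS = "NONPOLYMER_SUBCOMPONENTS"
GROUP = "GROUP"


class BirdError(ValueError):
    pass


@dataclass
class Subcomponent:
    """One chemical entity of a peptide-like molecule, identified against
    the dictionary."""

    key: str  # unique within the molecule, e.g. "A1"
    comp_id: str
    definition: Optional[ChemCompDef] = None

    @property
    def comp_type(self) -> str:
        return self.definition.comp_type if self.definition else "non-polymer"

    @property
    def is_peptide_like(self) -> bool:
        return "peptide" in self.comp_type.lower()

    @property
    def is_saccharide(self) -> bool:
        return "saccharide" in self.comp_type.lower()


@dataclass
class SubLink:
    """An inter-subcomponent covalent bond, by subcomponent key and atom name."""

    key1: str
    atom1: str
    key2: str
    atom2: str


@dataclass
class PeptideLikeMolecule:
    subcomponents: list[Subcomponent]
    links: list[SubLink]

    def sub(self, key: str) -> Subcomponent:
        for s in self.subcomponents:
            if s.key == key:
                return s
        raise KeyError(key)


@dataclass
class PeptideBond:
    """Directed carbonyl-C to amide-N bond between two subcomponents
    (direction follows the N-to-C chain direction: donor C first)."""

    c_key: str
    c_atom: str
    n_key: str
    n_atom: str


def _atom_element(cdef: Optional[ChemCompDef], atom_name: str) -> str:
    if cdef is None:
        # fall back on the element implied by the name's leading letters
        m = re.match(r"([A-Z]{1,2})", atom_name.upper())
        sym = m.group(1) if m else "X"
        if len(sym) == 2 and gemmi.Element(sym.capitalize()).atomic_number == 0:
            sym = sym[0]
        return sym.capitalize()
    try:
        return cdef.atom(atom_name).element
    except KeyError:
        return "X"


def _has_carbonyl(cdef: Optional[ChemCompDef], c_atom: str) -> bool:
    """Does this carbon carry a double-bonded oxygen within its own
    subcomponent?"""
    if cdef is None:
        return False
    for b in cdef.bonds:
        if c_atom in (b.atom_id_1, b.atom_id_2) and b.order == "DOUB":
            other = b.atom_id_2 if b.atom_id_1 == c_atom else b.atom_id_1
            if _atom_element(cdef, other) == "O":
                return True
    return False


def _n_bonded_to_carbon(cdef: Optional[ChemCompDef], n_atom: str) -> bool:
    if cdef is None:
        return False
    for b in cdef.bonds:
        if n_atom in (b.atom_id_1, b.atom_id_2):
            other = b.atom_id_2 if b.atom_id_1 == n_atom else b.atom_id_1
            if _atom_element(cdef, other) == "C":
                return True
    return False


def detect_peptide_bonds(molecule: PeptideLikeMolecule) -> list[PeptideBond]:
    """Peptide bonds among the molecule's inter-subcomponent links.

    A link qualifies when it joins a carbon to a nitrogen, the carbon carries
    a double-bonded oxygen (carbonyl) within its subcomponent, and the
    nitrogen is bonded to at least one carbon of its own (downstream)
    subcomponent.  Ester junctions (C-O-C, as in depsipeptides) fail the
    nitrogen criterion and are not peptide bonds.
    """
    bonds: list[PeptideBond] = []
    for link in molecule.links:
        s1, s2 = molecule.sub(link.key1), molecule.sub(link.key2)
        e1 = _atom_element(s1.definition, link.atom1)
        e2 = _atom_element(s2.definition, link.atom2)
        if {e1, e2} != {"C", "N"}:
            continue
        if e1 == "C":
            c_sub, c_atom, n_sub, n_atom = s1, link.atom1, s2, link.atom2
        else:
            c_sub, c_atom, n_sub, n_atom = s2, link.atom2, s1, link.atom1
        if not _has_carbonyl(c_sub.definition, c_atom):
            continue
        if not _n_bonded_to_carbon(n_sub.definition, n_atom):
            continue
        bonds.append(PeptideBond(c_key=c_sub.key, c_atom=c_atom, n_key=n_sub.key, n_atom=n_atom))
    return bonds


def max_consecutive_peptide_bonds(
    bonds: Sequence[PeptideBond], molecule: Optional[PeptideLikeMolecule] = None
) -> int:
    """Length of the longest run of peptide bonds traversing consecutive
    subcomponents.

    The bonds form a directed graph on subcomponents (C side to N side is
    the N-to-C direction reversed; direction does not affect run length).
    Branch points contribute their longest branch; cycles are traversed as
    simple paths."""
    if not bonds:
        return 0
    g = nx.DiGraph()
    for b in bonds:
        g.add_edge(b.c_key, b.n_key)

    best = 0

    def dfs(node: str, visited: frozenset, length: int) -> None:
        nonlocal best
        best = max(best, length)
        for nxt in list(g.successors(node)) + list(g.predecessors(node)):
            if nxt not in visited:
                dfs(nxt, visited | {nxt}, length + 1)

    for start in g.nodes:
        dfs(start, frozenset([start]), 0)
    return best


def _peptide_core_keys(molecule: PeptideLikeMolecule, bonds: Sequence[PeptideBond]) -> set[str]:
    """Peptide-bond participants plus amino-acid-type subcomponents; sugars
    and acyl chains never join the core even when amide-bonded to it (an
    N-acyl link is structurally a peptide bond but keeps the lipid an
    attachment)."""
    core = set()
    for b in bonds:
        for key in (b.c_key, b.n_key):
            sub = molecule.sub(key)
            if not (sub.is_saccharide or _is_lipid_like(sub)):
                core.add(key)
    core |= {s.key for s in molecule.subcomponents if s.is_peptide_like}
    return core


def _is_lipid_like(sub: Subcomponent) -> bool:
    """Fatty-acid / acyl-chain heuristic: a non-peptide subcomponent of four
    or more carbons with no nitrogen."""
    if sub.definition is None or sub.is_peptide_like:
        return False
    elements = [a.element for a in sub.definition.atoms]
    return elements.count("C") >= 4 and elements.count("N") == 0 and not sub.is_saccharide


def _nonpeptide_attachments(
    molecule: PeptideLikeMolecule, core: set[str]
) -> list[str]:
    """Subcomponents (sugars, fatty acids) covalently attached to the
    peptide core but not part of it."""
    attached = []
    for link in molecule.links:
        for key, other in ((link.key1, link.key2), (link.key2, link.key1)):
            if key in core or other not in core:
                continue
            sub = molecule.sub(key)
            if sub.is_saccharide or _is_lipid_like(sub):
                if sub.comp_id not in attached:
                    attached.append(sub.comp_id)
    return attached


def _sequence_n_to_c(
    molecule: PeptideLikeMolecule, bonds: Sequence[PeptideBond]
) -> list[str]:
    """Order the peptide subcomponents from the amino to the carboxy
    terminus along the peptide-bond path.

    A peptide bond runs carbonyl-C(i) -> amide-N(i+1), so chain direction
    follows the C->N edges.  For cyclic molecules with no free terminus the
    walk starts at the deterministic canonical rotation: the subcomponent
    with the lowest comp_id (ties broken by key order).
    """
    core_keys = [s.key for s in molecule.subcomponents
                 if s.is_peptide_like or s.key in _peptide_core_keys(molecule, bonds)]
    if not bonds:
        return [molecule.sub(k).comp_id for k in core_keys]
    succ: dict[str, list[str]] = {}
    has_incoming: set[str] = set()
    for b in bonds:
        succ.setdefault(b.c_key, []).append(b.n_key)
        has_incoming.add(b.n_key)
    starts = [k for k in core_keys if k in succ or k in has_incoming]
    free = [k for k in starts if k not in has_incoming]
    if free:
        start = sorted(free, key=lambda k: (molecule.sub(k).comp_id, k))[0]
    else:  # cyclic
        start = sorted(starts, key=lambda k: (molecule.sub(k).comp_id, k))[0]

    order = [start]
    seen = {start}
    node = start
    while True:
        nxts = [k for k in succ.get(node, []) if k not in seen]
        if not nxts:
            break
        node = sorted(nxts, key=lambda k: (molecule.sub(k).comp_id, k))[0]
        order.append(node)
        seen.add(node)
    # prepend any upstream residues reached against the arrows (branch safety)
    return [molecule.sub(k).comp_id for k in order]


@dataclass
class PeptideClassification:
    category: str
    max_consecutive_peptide_bonds: int
    subcomponent_sequence: list[str] = field(default_factory=list)
    nonpeptide_attachments: list[str] = field(default_factory=list)


def classify_peptide_like(molecule: PeptideLikeMolecule) -> PeptideClassification:
    """Apply the representation rules, in precedence order.

    Sugar or fatty-acid attachments on the peptide core force the group
    representation regardless of peptide-bond count (glycopeptides such as
    vancomycin-family antibiotics have cores with two or more consecutive
    peptide bonds yet are represented as groups).  Otherwise two or more
    consecutive peptide bonds make a polymer, and anything below that is a
    non-polymer with its subcomponent sequence recorded N to C.
    """
    bonds = detect_peptide_bonds(molecule)
    count = max_consecutive_peptide_bonds(bonds, molecule)
    core = _peptide_core_keys(molecule, bonds)
    attachments = _nonpeptide_attachments(molecule, core)
    sequence = _sequence_n_to_c(molecule, bonds)
    if attachments:
        return PeptideClassification(GROUP, count, sequence, attachments)
    if count >= 2:
        return PeptideClassification(POLYMER, count, sequence, [])
    return PeptideClassification(NONPOLYMER_SUBCOMPONENTS, count, sequence, [])


def molecule_from_components(
    components,  # Sequence[ObservedComponent]
    definitions: dict[str, ChemCompDef],
    links,  # Sequence[Linkage] restricted to these components
) -> PeptideLikeMolecule:
    """Assemble a PeptideLikeMolecule from observed components (already
    identified and renamed against the dictionary) and the covalent
    linkages detected among them."""
    subs = []
    key_of = {}
    for comp in components:
        key = f"{comp.auth_chain}{comp.auth_seq}{comp.ins_code}"
        key_of[comp.residue_key] = key
        subs.append(
            Subcomponent(key=key, comp_id=comp.comp_id,
                         definition=definitions.get(comp.comp_id))
        )
    sublinks = []
    for l in links:
        k1 = key_of.get((l.partner1.comp_id, l.partner1.auth_chain,
                         l.partner1.auth_seq, l.partner1.ins_code))
        k2 = key_of.get((l.partner2.comp_id, l.partner2.auth_chain,
                         l.partner2.auth_seq, l.partner2.ins_code))
        if k1 and k2 and k1 != k2:
            sublinks.append(SubLink(k1, l.partner1.atom_name, k2, l.partner2.atom_name))
    return PeptideLikeMolecule(subcomponents=subs, links=sublinks)


# ---------------------------------------------------------------------------
# PRD / FAM reference files

_PRD_ID_RE = re.compile(r"PRD_\d{6}")
_FAM_ID_RE = re.compile(r"FAM_\d{6}")


@dataclass
class PrdChain:
    chain_id: str
    comp_ids: list[str]


@dataclass
class PrdEntry:
    prd_id: str
    name: str = ""
    structural_class: str = ""
    function: str = ""
    chains: list[PrdChain] = field(default_factory=list)
    links: list[SubLink] = field(default_factory=list)
    source_refs: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not _PRD_ID_RE.fullmatch(self.prd_id):
            raise BirdError(f"malformed PRD identifier {self.prd_id!r}")


@dataclass
class PrdFamily:
    fam_id: str
    name: str = ""
    member_prd_ids: list[str] = field(default_factory=list)
    function: str = ""
    mechanism_of_action: str = ""
    pharmacology: str = ""

    def __post_init__(self):
        if not _FAM_ID_RE.fullmatch(self.fam_id):
            raise BirdError(f"malformed family identifier {self.fam_id!r}")
        if not self.member_prd_ids:
            raise BirdError(f"family {self.fam_id} has no members")


def _cat_rows(block, prefix):
    cat = block.get_mmcif_category(prefix, raw=False)
    if not cat:
        return []
    cols = list(cat)
    n = len(cat[cols[0]]) if cols else 0
    rows = []
    for i in range(n):
        # map CIF '?' (None) and '.' (False) to empty strings
        rows.append({c: (cat[c][i] if isinstance(cat[c][i], str) else "") for c in cols})
    return rows


def parse_prd(cif_text: str) -> PrdEntry:
    doc = gemmi.cif.read_string(cif_text)
    block = doc[0]
    mol = _cat_rows(block, "_pdbx_reference_molecule.")
    if not mol:
        raise BirdError("missing _pdbx_reference_molecule category")
    row = mol[0]
    entry = PrdEntry(
        prd_id=row["prd_id"],
        name=row.get("name", ""),
        structural_class=row.get("class", ""),
        function=row.get("type", ""),
    )
    chains: dict[str, PrdChain] = {}
    for r in _cat_rows(block, "_pdbx_reference_entity_poly_seq."):
        ch = chains.setdefault(r["ref_entity_id"], PrdChain(r["ref_entity_id"], []))
        ch.comp_ids.append(r["mon_id"])
    entry.chains = list(chains.values())
    for r in _cat_rows(block, "_pdbx_reference_entity_link."):
        entry.links.append(
            SubLink(key1=r["entity_id_1"], atom1=r["atom_id_1"],
                    key2=r["entity_id_2"], atom2=r["atom_id_2"])
        )
    for r in _cat_rows(block, "_pdbx_reference_molecule_source."):
        entry.source_refs.append(r.get("source", ""))
    return entry


def write_prd(entry: PrdEntry) -> str:
    doc = gemmi.cif.Document()
    block = doc.add_new_block(entry.prd_id)
    block.set_mmcif_category(
        "_pdbx_reference_molecule.",
        {
            "prd_id": [entry.prd_id],
            "name": [entry.name or None],
            "class": [entry.structural_class or None],
            "type": [entry.function or None],
        },
        raw=False,
    )
    if entry.chains:
        cat = {"ref_entity_id": [], "num": [], "mon_id": []}
        for ch in entry.chains:
            for i, comp in enumerate(ch.comp_ids, start=1):
                cat["ref_entity_id"].append(ch.chain_id)
                cat["num"].append(str(i))
                cat["mon_id"].append(comp)
        block.set_mmcif_category("_pdbx_reference_entity_poly_seq.", cat, raw=True)
    if entry.links:
        block.set_mmcif_category(
            "_pdbx_reference_entity_link.",
            {
                "link_id": [str(i + 1) for i in range(len(entry.links))],
                "entity_id_1": [l.key1 for l in entry.links],
                "atom_id_1": [l.atom1 for l in entry.links],
                "entity_id_2": [l.key2 for l in entry.links],
                "atom_id_2": [l.atom2 for l in entry.links],
            },
            raw=True,
        )
    if entry.source_refs:
        block.set_mmcif_category(
            "_pdbx_reference_molecule_source.",
            {
                "ordinal": [str(i + 1) for i in range(len(entry.source_refs))],
                "source": list(entry.source_refs),
            },
            raw=False,
        )
    return doc.as_string()


def parse_fam(cif_text: str) -> PrdFamily:
    doc = gemmi.cif.read_string(cif_text)
    block = doc[0]
    fam = _cat_rows(block, "_pdbx_reference_molecule_family.")
    if not fam:
        raise BirdError("missing _pdbx_reference_molecule_family category")
    row = fam[0]
    members = [r["prd_id"] for r in _cat_rows(block, "_pdbx_reference_molecule_list.")]
    return PrdFamily(
        fam_id=row["family_prd_id"],
        name=row.get("name", ""),
        member_prd_ids=members,
        function=row.get("function", ""),
        mechanism_of_action=row.get("mechanism_of_action", ""),
        pharmacology=row.get("pharmacology", ""),
    )


def write_fam(family: PrdFamily) -> str:
    doc = gemmi.cif.Document()
    block = doc.add_new_block(family.fam_id)
    block.set_mmcif_category(
        "_pdbx_reference_molecule_family.",
        {
            "family_prd_id": [family.fam_id],
            "name": [family.name or None],
            "function": [family.function or None],
            "mechanism_of_action": [family.mechanism_of_action or None],
            "pharmacology": [family.pharmacology or None],
        },
        raw=False,
    )
    block.set_mmcif_category(
        "_pdbx_reference_molecule_list.",
        {
            "family_prd_id": [family.fam_id] * len(family.member_prd_ids),
            "prd_id": list(family.member_prd_ids),
        },
        raw=True,
    )
    return doc.as_string()


def validate_family(family: PrdFamily, known_prd_ids: Sequence[str]) -> list[Issue]:
    """Check that every family member resolves to a loaded PRD entry."""
    known = set(known_prd_ids)
    return [
        Issue("fam-member-unknown", f"{family.fam_id}: unknown member {m}")
        for m in family.member_prd_ids
        if m not in known
    ]
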