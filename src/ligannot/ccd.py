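"""Chemical component dictionary (CCD) data model, reader, writer and validator.

The CCD describes every distinct chemical entity that can occur in a
macromolecular structure: one CIF block per component, carrying the atom
table (with leaving-atom flags and ideal/model coordinates), the bond table
with orders, and opaque chemical descriptors (SMILES/InChI).  This module
reads and writes that dialect, checks the internal consistency of a
definition, and exposes the component as a labeled molecular graph for
matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import networkx as nx

__all__ = [
    "AtomDef",
    "BondDef",
    "DescriptorDef",
    "ChemCompDef",
    "Issue",
    "CcdParseError",
    "CcdValidationError",
    "parse_ccd",
    "write_ccd",
    "validate_def",
    "component_graph",
    "parse_formula",
    "formula_from_atoms",
]

BOND_ORDERS = ("SING", "DOUB", "TRIP", "AROM")
DESCRIPTOR_TYPES = ("SMILES", "SMILES_CANONICAL", "InChI", "InChIKey", "SYSTEMATIC_NAME")

#: CIF categories owned by this module, in canonical output order.
_KNOWN_CATEGORIES = (
    "_chem_comp.",
    "_chem_comp_atom.",
    "_chem_comp_bond.",
    "_pdbx_chem_comp_descriptor.",
)


class CcdParseError(ValueError):
    """Raised for malformed CCD CIF input."""


class CcdValidationError(ValueError):
    """Raised when a definition violates the dictionary invariants."""


@dataclass
class Issue:
    """A machine-readable validation finding."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.code}] {self.message}"


@dataclass
class AtomDef:
    atom_id: str
    element: str
    charge: int = 0
    aromatic: bool = False
    stereo_config: str = "N"
    leaving: bool = False
    ideal_xyz: Optional[tuple[float, float, float]] = None
    model_xyz: Optional[tuple[float, float, float]] = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class BondDef:
    atom_id_1: str
    atom_id_2: str
    order: str = "SING"
    aromatic: bool = False
    stereo: str = "N"

    def key(self) -> frozenset[str]:
        return frozenset((self.atom_id_1, self.atom_id_2))


@dataclass
class DescriptorDef:
    desc_type: str
    program: str
    value: str


@dataclass
class ChemCompDef:
    """One chemical component definition (one CIF block of the dictionary)."""

    comp_id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    formula: str = ""
    formula_weight: Optional[float] = None
    formal_charge: int = 0
    comp_type: str = "non-polymer"
    pdbx_type: str = "HETAIN"
    parent_comp_ids: list[str] = field(default_factory=list)
    atoms: list[AtomDef] = field(default_factory=list)
    bonds: list[BondDef] = field(default_factory=list)
    descriptors: list[DescriptorDef] = field(default_factory=list)
    release_status: str = "REL"
    #: unknown CIF categories preserved verbatim for round-trip
    extra_categories: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def atom(self, atom_id: str) -> AtomDef:
        for a in self.atoms:
            if a.atom_id == atom_id:
                return a
        raise KeyError(atom_id)

    def heavy_atoms(self) -> list[AtomDef]:
        return [a for a in self.atoms if not a.is_hydrogen]


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-order formula string like ``C6 H12 O6`` into element counts."""
    counts: dict[str, int] = {}
    for token in formula.replace(" ", " ").split():
        m = _FORMULA_TOKEN.fullmatch(token)
        if m is None:
            raise CcdParseError(f"unparsable formula token {token!r} in {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    return counts


def formula_from_atoms(atoms: Iterable[AtomDef]) -> str:
    """Hill-order formula (C, H, then alphabetical) derived from an atom list."""
    counts: dict[str, int] = {}
    for a in atoms:
        el = "H" if a.element == "D" else a.element
        counts[el] = counts.get(el, 0) + 1
    parts = []
    for el in ("C", "H"):
        if el in counts:
            n = counts.pop(el)
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(counts):
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return " ".join(parts)


def _is_missing(v: Optional[str]) -> bool:
    return v is None or v in (".", "?", "")


def _unquote(v: str) -> str:
    if len(v) >= 2 and v[0] == v[-1] and v[0] in "'\"":
        return v[1:-1]
    return v


def _yn(v: Optional[str]) -> bool:
    return not _is_missing(v) and _unquote(v).upper() == "Y"


def _xyz(row: dict[str, str], xtag: str, ytag: str, ztag: str):
    vals = [row.get(t) for t in (xtag, ytag, ztag)]
    if any(_is_missing(v) for v in vals):
        return None
    return tuple(float(v) for v in vals)


def _category_rows(block: gemmi.cif.Block, prefix: str) -> list[dict[str, str]]:
    cat = block.get_mmcif_category(prefix, raw=True)
    if not cat:
        return []
    cols = list(cat.keys())
    n = len(cat[cols[0]]) if cols else 0
    return [{c: cat[c][i] for c in cols} for i in range(n)]


def _parse_block(block: gemmi.cif.Block) -> ChemCompDef:
    comp_rows = _category_rows(block, "_chem_comp.")
    if not comp_rows:
        raise CcdParseError(f"block {block.name!r} has no _chem_comp category")
    row = comp_rows[0]
    comp_id = _unquote(row.get("id") or block.name).upper()

    synonyms: list[str] = []
    syn = row.get("pdbx_synonyms")
    if not _is_missing(syn):
        synonyms = [s.strip() for s in _unquote(syn).split(";") if s.strip()]

    parents: list[str] = []
    par = row.get("mon_nstd_parent_comp_id")
    if not _is_missing(par):
        parents = [p.strip().upper() for p in _unquote(par).split(",") if p.strip()]

    cdef = ChemCompDef(
        comp_id=comp_id,
        name=_unquote(row["name"]) if not _is_missing(row.get("name")) else "",
        synonyms=synonyms,
        formula=_unquote(row["formula"]) if not _is_missing(row.get("formula")) else "",
        formula_weight=(
            float(row["formula_weight"]) if not _is_missing(row.get("formula_weight")) else None
        ),
        formal_charge=(
            int(row["pdbx_formal_charge"]) if not _is_missing(row.get("pdbx_formal_charge")) else 0
        ),
        comp_type=_unquote(row["type"]) if not _is_missing(row.get("type")) else "non-polymer",
        pdbx_type=_unquote(row["pdbx_type"]) if not _is_missing(row.get("pdbx_type")) else "HETAIN",
        parent_comp_ids=parents,
        release_status=(
            _unquote(row["pdbx_release_status"])
            if not _is_missing(row.get("pdbx_release_status"))
            else "REL"
        ),
    )

    for arow in _category_rows(block, "_chem_comp_atom."):
        cdef.atoms.append(
            AtomDef(
                atom_id=_unquote(arow["atom_id"]),
                element=_unquote(arow.get("type_symbol", "X")).capitalize(),
                charge=int(arow["charge"]) if not _is_missing(arow.get("charge")) else 0,
                aromatic=_yn(arow.get("pdbx_aromatic_flag")),
                stereo_config=(
                    _unquote(arow["pdbx_stereo_config"]).upper()
                    if not _is_missing(arow.get("pdbx_stereo_config"))
                    else "N"
                ),
                leaving=_yn(arow.get("pdbx_leaving_atom_flag")),
                model_xyz=_xyz(arow, "model_Cartn_x", "model_Cartn_y", "model_Cartn_z"),
                ideal_xyz=_xyz(
                    arow,
                    "pdbx_model_Cartn_x_ideal",
                    "pdbx_model_Cartn_y_ideal",
                    "pdbx_model_Cartn_z_ideal",
                ),
            )
        )

    atom_ids = {a.atom_id for a in cdef.atoms}
    for brow in _category_rows(block, "_chem_comp_bond."):
        b = BondDef(
            atom_id_1=_unquote(brow["atom_id_1"]),
            atom_id_2=_unquote(brow["atom_id_2"]),
            order=(
                _unquote(brow["value_order"]).upper()
                if not _is_missing(brow.get("value_order"))
                else "SING"
            ),
            aromatic=_yn(brow.get("pdbx_aromatic_flag")),
            stereo=(
                _unquote(brow["pdbx_stereo_config"]).upper()
                if not _is_missing(brow.get("pdbx_stereo_config"))
                else "N"
            ),
        )
        for aid in (b.atom_id_1, b.atom_id_2):
            if aid not in atom_ids:
                raise CcdValidationError(
                    f"component {comp_id}: bond references unknown atom {aid!r}"
                )
        cdef.bonds.append(b)

    for drow in _category_rows(block, "_pdbx_chem_comp_descriptor."):
        cdef.descriptors.append(
            DescriptorDef(
                desc_type=_unquote(drow.get("type", "")),
                program=_unquote(drow.get("program", "")) if not _is_missing(drow.get("program")) else "",
                value=_unquote(drow.get("descriptor", "")),
            )
        )

    # preserve everything we do not model, for byte-level-equivalent round trips
    for prefix in block.get_mmcif_category_names():
        if prefix not in _KNOWN_CATEGORIES:
            cdef.extra_categories[prefix] = block.get_mmcif_category(prefix, raw=True)

    return cdef


def parse_ccd(cif_text: str) -> list[ChemCompDef]:
    """Parse a CCD CIF document into a list of component definitions.

    Raises :class:`CcdParseError` on malformed CIF syntax and
    :class:`CcdValidationError` when a bond references an atom that is not
    in the component's atom table.  Other invariant violations are reported
    by :func:`validate_def`, not silently repaired here.
    """
    try:
        doc = gemmi.cif.read_string(cif_text)
    except (ValueError, RuntimeError) as exc:
        raise CcdParseError(str(exc)) from exc
    defs = []
    for block in doc:
        if block.get_mmcif_category("_chem_comp.") or block.name:
            if not block.get_mmcif_category_names():
                continue
            defs.append(_parse_block(block))
    return defs


def write_ccd(defs: Sequence[ChemCompDef]) -> str:
    """Serialize definitions back to CCD CIF text.

    Atoms and bonds keep their input order; categories are written in the
    canonical dictionary order.  Definitions that fail :func:`validate_def`
    are refused.
    """
    problems = []
    for cdef in defs:
        issues = validate_def(cdef)
        if issues:
            problems.append(f"{cdef.comp_id}: " + "; ".join(str(i) for i in issues))
    if problems:
        raise CcdValidationError("refusing to write invalid definitions: " + " | ".join(problems))

    doc = gemmi.cif.Document()
    for cdef in defs:
        block = doc.add_new_block(f"comp_{cdef.comp_id}")
        comp = {
            "id": [cdef.comp_id],
            "name": [cdef.name or None],
            "type": [cdef.comp_type],
            "pdbx_type": [cdef.pdbx_type],
            "formula": [cdef.formula or None],
            "mon_nstd_parent_comp_id": [",".join(cdef.parent_comp_ids) or None],
            "pdbx_synonyms": ["; ".join(cdef.synonyms) or None],
            "pdbx_formal_charge": [str(cdef.formal_charge)],
            "formula_weight": [
                f"{cdef.formula_weight:.3f}" if cdef.formula_weight is not None else None
            ],
            "pdbx_release_status": [cdef.release_status],
        }
        block.set_mmcif_category("_chem_comp.", comp, raw=False)

        if cdef.atoms:
            def fmt(x: Optional[tuple], i: int) -> Optional[str]:
                return None if x is None else f"{x[i]:.3f}"

            atoms = {
                "comp_id": [cdef.comp_id] * len(cdef.atoms),
                "atom_id": [a.atom_id for a in cdef.atoms],
                "type_symbol": [a.element.upper() for a in cdef.atoms],
                "charge": [str(a.charge) for a in cdef.atoms],
                "pdbx_aromatic_flag": ["Y" if a.aromatic else "N" for a in cdef.atoms],
                "pdbx_leaving_atom_flag": ["Y" if a.leaving else "N" for a in cdef.atoms],
                "pdbx_stereo_config": [a.stereo_config for a in cdef.atoms],
                "model_Cartn_x": [fmt(a.model_xyz, 0) for a in cdef.atoms],
                "model_Cartn_y": [fmt(a.model_xyz, 1) for a in cdef.atoms],
                "model_Cartn_z": [fmt(a.model_xyz, 2) for a in cdef.atoms],
                "pdbx_model_Cartn_x_ideal": [fmt(a.ideal_xyz, 0) for a in cdef.atoms],
                "pdbx_model_Cartn_y_ideal": [fmt(a.ideal_xyz, 1) for a in cdef.atoms],
                "pdbx_model_Cartn_z_ideal": [fmt(a.ideal_xyz, 2) for a in cdef.atoms],
            }
            block.set_mmcif_category("_chem_comp_atom.", atoms, raw=False)

        if cdef.bonds:
            bonds = {
                "comp_id": [cdef.comp_id] * len(cdef.bonds),
                "atom_id_1": [b.atom_id_1 for b in cdef.bonds],
                "atom_id_2": [b.atom_id_2 for b in cdef.bonds],
                "value_order": [b.order for b in cdef.bonds],
                "pdbx_aromatic_flag": ["Y" if b.aromatic else "N" for b in cdef.bonds],
                "pdbx_stereo_config": [b.stereo for b in cdef.bonds],
            }
            block.set_mmcif_category("_chem_comp_bond.", bonds, raw=False)

        if cdef.descriptors:
            desc = {
                "comp_id": [cdef.comp_id] * len(cdef.descriptors),
                "type": [d.desc_type for d in cdef.descriptors],
                "program": [d.program or None for d in cdef.descriptors],
                "descriptor": [d.value for d in cdef.descriptors],
            }
            block.set_mmcif_category("_pdbx_chem_comp_descriptor.", desc, raw=False)

        for prefix, cat in cdef.extra_categories.items():
            block.set_mmcif_category(prefix, cat, raw=True)

    return doc.as_string()


_COMP_ID_RE = re.compile(r"[A-Z0-9]{1,3}")


def validate_def(cdef: ChemCompDef) -> list[Issue]:
    """Check a definition against the dictionary invariants.

    Returns an empty list iff the definition is internally consistent;
    otherwise one :class:`Issue` per violation.
    """
    issues: list[Issue] = []

    if not _COMP_ID_RE.fullmatch(cdef.comp_id or ""):
        issues.append(
            Issue("comp-id", f"component id {cdef.comp_id!r} is not 1-3 uppercase alphanumerics")
        )

    seen: set[str] = set()
    for a in cdef.atoms:
        if not a.atom_id:
            issues.append(Issue("atom-id-empty", f"{cdef.comp_id}: empty atom_id"))
        elif a.atom_id in seen:
            issues.append(Issue("atom-id-dup", f"{cdef.comp_id}: duplicate atom_id {a.atom_id!r}"))
        seen.add(a.atom_id)
        if gemmi.Element(a.element).atomic_number == 0:
            issues.append(
                Issue("element", f"{cdef.comp_id}/{a.atom_id}: unknown element {a.element!r}")
            )
        if a.stereo_config not in ("N", "R", "S"):
            issues.append(
                Issue("stereo", f"{cdef.comp_id}/{a.atom_id}: stereo_config {a.stereo_config!r}")
            )

    bond_keys: set[frozenset[str]] = set()
    for b in cdef.bonds:
        if b.atom_id_1 == b.atom_id_2:
            issues.append(Issue("bond-self", f"{cdef.comp_id}: self-bond on {b.atom_id_1!r}"))
        for aid in (b.atom_id_1, b.atom_id_2):
            if aid not in seen:
                issues.append(
                    Issue("bond-dangling", f"{cdef.comp_id}: bond references unknown atom {aid!r}")
                )
        if b.key() in bond_keys:
            issues.append(
                Issue(
                    "bond-dup",
                    f"{cdef.comp_id}: duplicate bond {b.atom_id_1}-{b.atom_id_2}",
                )
            )
        bond_keys.add(b.key())
        if b.order not in BOND_ORDERS:
            issues.append(Issue("bond-order", f"{cdef.comp_id}: bad bond order {b.order!r}"))

    if cdef.formula:
        try:
            declared = parse_formula(cdef.formula)
        except CcdParseError as exc:
            issues.append(Issue("formula-syntax", str(exc)))
        else:
            derived = parse_formula(formula_from_atoms(cdef.atoms)) if cdef.atoms else {}
            if declared != derived:
                issues.append(
                    Issue(
                        "formula-mismatch",
                        f"{cdef.comp_id}: formula says {declared}, atoms give {derived}",
                    )
                )

    charge_sum = sum(a.charge for a in cdef.atoms)
    if cdef.atoms and charge_sum != cdef.formal_charge:
        issues.append(
            Issue(
                "charge-mismatch",
                f"{cdef.comp_id}: formal_charge {cdef.formal_charge} != atom sum {charge_sum}",
            )
        )

    for d in cdef.descriptors:
        if not d.value:
            issues.append(Issue("descriptor-empty", f"{cdef.comp_id}: empty {d.desc_type} value"))

    return issues


def component_graph(
    cdef: ChemCompDef,
    include_hydrogens: bool = True,
    include_leaving: bool = True,
) -> nx.Graph:
    """Molecular graph of a definition: nodes keyed by atom name, labeled by
    element; edges labeled by bond order.

    Hydrogens and/or leaving atoms can be excluded, together with their
    incident bonds — that is the form used when matching observed ligands,
    where hydrogens are unresolved and leaving atoms may have been eliminated
    by covalent attachment.
    """
    g = nx.Graph(comp_id=cdef.comp_id)
    keep: set[str] = set()
    for a in cdef.atoms:
        if not include_hydrogens and a.is_hydrogen:
            continue
        if not include_leaving and a.leaving:
            continue
        keep.add(a.atom_id)
        g.add_node(a.atom_id, element=a.element, leaving=a.leaving)
    for b in cdef.bonds:
        if b.atom_id_1 in keep and b.atom_id_2 in keep:
            g.add_edge(b.atom_id_1, b.atom_id_2, order=b.order, aromatic=b.aromatic)
    return g
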