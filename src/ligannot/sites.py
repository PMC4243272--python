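"""Ligand binding-site delineation.

A binding site is the set of residues having any atom within a fixed cutoff
(3.7 A by default) of any atom of a ligand, with crystallographic symmetry
taken into account.  Multi-component molecules (oligosaccharides, peptide-like
groups) are treated as one ligand so the site describes the environment of the
whole molecule rather than of the individual moieties.  Sites carry unique
alphanumeric identifiers (AC1 ... ZZ9) and serialize to the ``_struct_site`` /
``_struct_site_gen`` category pair.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .structure import (
    AtomSite,
    MissingCellError,
    ObservedComponent,
    ResidueKey,
    StructureModel,
    expand_symmetry,
)

__all__ = [
    "SiteParams",
    "SiteContact",
    "BindingSite",
    "SiteError",
    "delineate_sites",
    "assign_site_ids",
    "write_struct_site",
    "parse_struct_site",
    "IDENTITY_SYM_LABEL",
]

IDENTITY_SYM_LABEL = "1_555"


class SiteError(ValueError):
    pass


@dataclass
class SiteParams:
    cutoff: float = 3.7
    include_waters_as_neighbors: bool = True
    use_symmetry: Optional[bool] = None  # None = auto: on when a cell is present

    def __post_init__(self):
        if self.cutoff <= 0:
            raise SiteError("cutoff must be positive")


@dataclass
class SiteContact:
    residue: ResidueKey
    sym_label: str
    min_distance: float


@dataclass
class BindingSite:
    site_id: str
    ligand: list[ObservedComponent]
    contacts: list[SiteContact] = field(default_factory=list)
    evidence: str = "Software"
    details: Optional[str] = None

    @property
    def ligand_keys(self) -> set[ResidueKey]:
        return {c.residue_key for c in self.ligand}


def assign_site_ids(n: int) -> list[str]:
    """The first n identifiers of the AC1 ... ZZ9 scheme.

    Two uppercase letters and a digit 1-9; the digit cycles fastest, then the
    second letter, then the first, starting from AC1 (AC1..AC9, AD1.., skipping
    the AA/AB prefixes).  Deterministic and never reused within a structure.
    """
    if n < 0:
        raise SiteError("site count must be non-negative")
    if n == 0:
        return []
    letters = string.ascii_uppercase
    capacity = (26 * 26 - 2) * 9
    if n > capacity:
        raise SiteError(f"site-id scheme capacity {capacity} exceeded ({n} requested)")
    ids = []
    for first in letters:
        for second in letters:
            if first == "A" and second in ("A", "B"):
                continue
            for digit in range(1, 10):
                ids.append(f"{first}{second}{digit}")
                if len(ids) == n:
                    return ids
    return ids


def _group_ligands(
    model: StructureModel, groups: Optional[dict[ResidueKey, str]] = None
) -> list[list[ObservedComponent]]:
    """Partition the model's ligands into site subjects: one group per
    declared multi-component molecule, one singleton per remaining ligand,
    ordered by author addressing of the first member."""
    grouped: dict[str, list[ObservedComponent]] = {}
    singles: list[list[ObservedComponent]] = []
    for comp in model.ligands():
        gid = comp.group_id
        if groups and comp.residue_key in groups:
            gid = groups[comp.residue_key]
        if gid:
            grouped.setdefault(gid, []).append(comp)
        else:
            singles.append([comp])
    result = list(grouped.values()) + singles
    result.sort(key=lambda g: (g[0].auth_chain, g[0].auth_seq, g[0].ins_code))
    return result


def _contacts_for_group(
    model: StructureModel,
    group: list[ObservedComponent],
    params: SiteParams,
) -> list[SiteContact]:
    ligand_atoms = [a for comp in group for a in comp.atoms]
    own_keys = {comp.residue_key for comp in group}
    use_sym = params.use_symmetry
    if use_sym is None:
        use_sym = model.cell is not None
    if use_sym and model.cell is None:
        raise MissingCellError("symmetry-aware site delineation requires a cell")

    best: dict[tuple[ResidueKey, str], float] = {}
    if use_sym:
        for img in expand_symmetry(model, ligand_atoms, params.cutoff):
            key = img.source.residue_key
            if key in own_keys and img.sym_label == IDENTITY_SYM_LABEL:
                continue
            k = (key, img.sym_label)
            if img.distance < best.get(k, math.inf):
                best[k] = img.distance
    else:
        lig_ids = {id(a) for a in ligand_atoms}
        lig_xyz = np.array([a.xyz for a in ligand_atoms])
        for atom in model.atom_sites:
            if id(atom) in lig_ids or atom.residue_key in own_keys:
                continue
            d = float(np.min(np.linalg.norm(lig_xyz - np.asarray(atom.xyz), axis=1)))
            if d <= params.cutoff:
                k = (atom.residue_key, IDENTITY_SYM_LABEL)
                if d < best.get(k, math.inf):
                    best[k] = d

    contacts = []
    for (key, sym_label), dist in best.items():
        comp_id = key[0]
        if not params.include_waters_as_neighbors and comp_id in ("HOH", "DOD", "WAT"):
            continue
        contacts.append(SiteContact(residue=key, sym_label=sym_label, min_distance=dist))
    contacts.sort(key=lambda c: (c.residue[1], c.residue[2], c.residue[3], c.sym_label))
    return contacts


def delineate_sites(
    model: StructureModel,
    params: Optional[SiteParams] = None,
    groups: Optional[dict[ResidueKey, str]] = None,
    details: Optional[dict[str, str]] = None,
) -> list[BindingSite]:
    """One binding site per non-polymeric, non-water ligand (or per declared
    multi-component group), listing every residue with any atom — or symmetry
    image of an atom — within the cutoff of any ligand atom.

    Contacts are deduplicated at residue level per symmetry image, keeping
    the minimum distance; residues of the ligand's own group are never its
    contacts.  ``details`` maps site_id to author-provided catalytic-site
    text.
    """
    params = params or SiteParams()
    subjects = _group_ligands(model, groups)
    ids = assign_site_ids(len(subjects))
    sites = []
    for site_id, group in zip(ids, subjects):
        site = BindingSite(
            site_id=site_id,
            ligand=group,
            contacts=_contacts_for_group(model, group, params),
            details=(details or {}).get(site_id),
        )
        sites.append(site)
    return sites


def write_struct_site(sites: Sequence[BindingSite]) -> str:
    """Serialize sites to mmCIF ``_struct_site`` + ``_struct_site_gen``.

    One ``_struct_site`` row per site and one ``_struct_site_gen`` row per
    contact, joined by the site identifier.  An empty site list produces an
    empty document (both categories absent).
    """
    seen = set()
    for s in sites:
        if s.site_id in seen:
            raise SiteError(f"duplicate site_id {s.site_id!r}")
        seen.add(s.site_id)

    doc = gemmi.cif.Document()
    block = doc.add_new_block("sites")
    if sites:
        lig_desc = []
        for s in sites:
            parts = [f"{c.comp_id} {c.auth_chain} {c.auth_seq}{c.ins_code}" for c in s.ligand]
            lig_desc.append("BINDING SITE FOR " + " + ".join(parts))
        block.set_mmcif_category(
            "_struct_site.",
            {
                "id": [s.site_id for s in sites],
                "pdbx_evidence_code": [s.evidence for s in sites],
                "pdbx_num_residues": [str(len(s.contacts)) for s in sites],
                "details": [s.details if s.details else d for s, d in zip(sites, lig_desc)],
            },
        )
        rows = [(s.site_id, c) for s in sites for c in s.contacts]
        if rows:
            block.set_mmcif_category(
                "_struct_site_gen.",
                {
                    "id": [str(i + 1) for i in range(len(rows))],
                    "site_id": [sid for sid, _ in rows],
                    "auth_comp_id": [c.residue[0] for _, c in rows],
                    "auth_asym_id": [c.residue[1] for _, c in rows],
                    "auth_seq_id": [str(c.residue[2]) for _, c in rows],
                    "pdbx_auth_ins_code": [c.residue[3] or "?" for _, c in rows],
                    "symmetry": [c.sym_label for _, c in rows],
                    "details": [f"{c.min_distance:.3f}" for _, c in rows],
                },
            )
    return doc.as_string()


def parse_struct_site(cif_text: str) -> list[BindingSite]:
    """Read back the category pair written by :func:`write_struct_site`.

    Ligand membership is not stored in the categories, so the returned sites
    carry identifiers, details and contacts only."""
    doc = gemmi.cif.read_string(cif_text)
    block = doc[0] if len(doc) else None
    sites: list[BindingSite] = []
    if block is None:
        return sites
    cat = block.get_mmcif_category("_struct_site.", raw=False)
    if not cat:
        return sites
    by_id: dict[str, BindingSite] = {}
    for i, sid in enumerate(cat["id"]):
        details = cat.get("details", [None] * len(cat["id"]))[i]
        site = BindingSite(
            site_id=sid,
            ligand=[],
            evidence=cat.get("pdbx_evidence_code", ["Software"] * len(cat["id"]))[i],
            details=details if details else None,
        )
        by_id[sid] = site
        sites.append(site)
    gen = block.get_mmcif_category("_struct_site_gen.", raw=False)
    if gen:
        n = len(gen["site_id"])
        for i in range(n):
            sid = gen["site_id"][i]
            if sid not in by_id:
                raise SiteError(f"_struct_site_gen.site_id {sid!r} missing from _struct_site")
            ins = gen.get("pdbx_auth_ins_code", [""] * n)[i]
            by_id[sid].contacts.append(
                SiteContact(
                    residue=(
                        gen["auth_comp_id"][i],
                        gen["auth_asym_id"][i],
                        int(gen["auth_seq_id"][i]),
                        "" if ins in (None, "?", ".", False) else ins,
                    ),
                    sym_label=gen["symmetry"][i],
                    min_distance=float(gen["details"][i]),
                )
            )
    return sites
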