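"""Covalent linkages between components and metal-coordination annotation.

Inter-component atom pairs within covalent range become ``_struct_conn``
records: disulfide bridges between cysteine sulfurs, metal-coordination
(metalc) links between a metal and its donor atoms, and covalent (covale)
links for everything else — with standard polymer backbone bonds (peptide
C-N between sequence neighbors, nucleic O3'-P) excluded.  For every metal
center all pairwise ligator-metal-ligator angles are computed and written
both as a PDB REMARK 620 block and as mmCIF ``_pdbx_struct_conn_angle``
rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .matcher import BOND_TOLERANCE, covalent_radius
from .sites import IDENTITY_SYM_LABEL
from .structure import (
    AtomSite,
    ObservedComponent,
    StructureModel,
    expand_symmetry,
)

__all__ = [
    "AtomRef",
    "Linkage",
    "CoordinationCenter",
    "LinkageError",
    "detect_linkages",
    "coordination_center",
    "find_metal_sites",
    "write_struct_conn",
    "write_remark620",
    "parse_remark620",
    "write_conn_angle",
    "parse_conn_angle",
    "SUPPORTED_METALS",
    "METAL_CUTOFFS",
    "DEFAULT_METAL_CUTOFF",
]

SUPPORTED_METALS = frozenset(
    "ZN MG CA FE MN NA K CU NI CO CD HG MO W LI".split()
)

#: coordination-sphere cutoffs (A) by (metal, donor-element) pair; chemistry
#: practice values, configurable per call.
METAL_CUTOFFS: dict[tuple[str, str], float] = {
    ("ZN", "N"): 2.6, ("ZN", "O"): 2.6, ("ZN", "S"): 2.8,
    ("MG", "O"): 2.6, ("MG", "N"): 2.6,
    ("CA", "O"): 2.9, ("CA", "N"): 2.9,
    ("NA", "O"): 3.2, ("NA", "N"): 3.2,
    ("K", "O"): 3.2, ("K", "N"): 3.2,
}
DEFAULT_METAL_CUTOFF = 3.0

#: donor elements considered as potential ligators
DONOR_ELEMENTS = frozenset("N O S F CL BR I".split())


class LinkageError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRef:
    comp_id: str
    auth_chain: str
    auth_seq: int
    ins_code: str
    atom_name: str
    alt_loc: str = ""
    sym_label: str = IDENTITY_SYM_LABEL

    @classmethod
    def from_site(cls, a: AtomSite, sym_label: str = IDENTITY_SYM_LABEL) -> "AtomRef":
        return cls(a.comp_id, a.auth_chain, a.auth_seq, a.ins_code, a.atom_name,
                   a.alt_loc, sym_label)

    def residue_str(self) -> str:
        return f"{self.comp_id} {self.auth_chain} {self.auth_seq}{self.ins_code}"


@dataclass
class Linkage:
    kind: str  # covale | metalc | disulf
    partner1: AtomRef
    partner2: AtomRef
    distance: float


def metal_cutoff(metal_el: str, donor_el: str,
                 table: Optional[dict[tuple[str, str], float]] = None) -> float:
    table = METAL_CUTOFFS if table is None else table
    return table.get((metal_el.upper(), donor_el.upper()), DEFAULT_METAL_CUTOFF)


def _backbone_pair(model: StructureModel, a: AtomSite, b: AtomSite) -> bool:
    """Standard polymer backbone bond between sequence-adjacent residues:
    peptide C-N or nucleic O3'-P.  Checked on author numbering so genuine
    nonstandard cross-links are retained."""
    try:
        ca = model.component(a.residue_key)
        cb = model.component(b.residue_key)
    except KeyError:
        return False
    if not model.sequence_neighbors(ca, cb):
        return False
    names = {a.atom_name, b.atom_name}
    return names == {"C", "N"} or names == {"O3'", "P"}


def _max_reach(elements: set[str]) -> float:
    rmax = max(covalent_radius(e) for e in elements)
    return 2 * rmax + BOND_TOLERANCE


def detect_linkages(
    model: StructureModel,
    tolerance: float = BOND_TOLERANCE,
    use_symmetry: Optional[bool] = None,
    metal_cutoffs: Optional[dict[tuple[str, str], float]] = None,
) -> list[Linkage]:
    """Inter-component covalent, disulfide and metal-coordination links.

    Applies the covalent-radius criterion across component boundaries
    (symmetry-aware when a cell is present), excludes standard backbone
    bonds, and classifies: Cys S-S pairs as disulf, metal-donor pairs within
    the coordination cutoff as metalc, everything else as covale.
    """
    heavy = [a for a in model.atom_sites if not a.is_hydrogen]
    if not heavy:
        return []
    elements = {a.element for a in heavy}
    reach = max(_max_reach(elements), DEFAULT_METAL_CUTOFF,
                *(metal_cutoffs or METAL_CUTOFFS).values())

    use_sym = use_symmetry if use_symmetry is not None else model.cell is not None

    pairs: dict[tuple, Linkage] = {}

    def consider(a: AtomSite, b: AtomSite, dist: float, sym_label: str) -> None:
        if a.residue_key == b.residue_key and sym_label == IDENTITY_SYM_LABEL:
            return
        if a.is_hydrogen or b.is_hydrogen:
            return
        a_metal = a.element.upper() in SUPPORTED_METALS
        b_metal = b.element.upper() in SUPPORTED_METALS
        kind = None
        if a_metal != b_metal:
            metal, donor = (a, b) if a_metal else (b, a)
            if donor.element.upper() in DONOR_ELEMENTS and dist <= metal_cutoff(
                metal.element, donor.element, metal_cutoffs
            ):
                kind = "metalc"
        if kind is None:
            if dist > covalent_radius(a.element) + covalent_radius(b.element) + tolerance:
                return
            if _backbone_pair(model, a, b):
                return
            if (
                {a.element, b.element} == {"S"}
                and a.comp_id == "CYS"
                and b.comp_id == "CYS"
            ):
                kind = "disulf"
            else:
                kind = "covale"
        r1 = AtomRef.from_site(a)
        r2 = AtomRef.from_site(b, sym_label)
        key = tuple(sorted([(r1, IDENTITY_SYM_LABEL), (r2, sym_label)],
                           key=lambda t: (t[0].auth_chain, t[0].auth_seq, t[0].atom_name,
                                          t[0].alt_loc, t[1])))
        pkey = (key[0][0].residue_str(), key[0][0].atom_name, key[0][0].alt_loc,
                key[1][0].residue_str(), key[1][0].atom_name, key[1][0].alt_loc, sym_label)
        if pkey not in pairs or dist < pairs[pkey].distance:
            pairs[pkey] = Linkage(kind=kind, partner1=r1, partner2=r2, distance=dist)

    coords = np.array([a.xyz for a in heavy])
    for i in range(len(heavy)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for off in np.nonzero(d <= reach)[0]:
            j = i + 1 + off
            a, b = heavy[i], heavy[j]
            if a.residue_key == b.residue_key:
                continue
            if a.alt_loc and b.alt_loc and a.alt_loc != b.alt_loc:
                continue
            consider(a, b, float(d[off]), IDENTITY_SYM_LABEL)

    if use_sym and model.cell is not None:
        for img in expand_symmetry(model, heavy, reach, atoms=heavy):
            if img.sym_label == IDENTITY_SYM_LABEL:
                continue  # direct pairs already covered
            src = img.source
            img_xyz = np.asarray(img.atom.xyz)
            for k, a in enumerate(heavy):
                if a.alt_loc and src.alt_loc and a.alt_loc != src.alt_loc:
                    continue
                dist = float(np.linalg.norm(coords[k] - img_xyz))
                if dist <= reach and dist > 1e-6:
                    consider(a, img.atom, dist, img.sym_label)

    return sorted(
        pairs.values(),
        key=lambda l: (l.partner1.auth_chain, l.partner1.auth_seq, l.partner1.atom_name,
                       l.partner2.auth_chain, l.partner2.auth_seq, l.partner2.atom_name),
    )


@dataclass
class Ligator:
    atom: AtomRef
    distance: float
    xyz: tuple[float, float, float]


@dataclass
class CoordinationCenter:
    metal: AtomRef
    metal_xyz: tuple[float, float, float]
    ligators: list[Ligator] = field(default_factory=list)
    #: (i, j, degrees) over ligator indices, i < j, all k(k-1)/2 pairs
    angles: list[tuple[int, int, float]] = field(default_factory=list)


def _angle_deg(m: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    v1, v2 = p - m, q - m
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def coordination_center(
    model: StructureModel,
    metal: AtomSite,
    cutoffs: Optional[dict[tuple[str, str], float]] = None,
    use_symmetry: Optional[bool] = None,
) -> CoordinationCenter:
    """Delineate one metal coordination sphere and compute all pairwise
    ligator-metal-ligator angles.

    Ligators are N/O/S (and halide) atoms within the element-pair cutoff,
    symmetry-aware when a cell is present; alternate conformers contribute
    separate ligators, and angles are reported for every ligator pair
    including cross-conformer pairs.
    """
    el = metal.element.upper()
    if el not in SUPPORTED_METALS:
        raise LinkageError(f"unsupported metal element {metal.element!r}")
    use_sym = use_symmetry if use_symmetry is not None else model.cell is not None
    max_cut = max(
        [metal_cutoff(el, d, cutoffs) for d in DONOR_ELEMENTS]
        + [DEFAULT_METAL_CUTOFF]
    )
    m_xyz = np.asarray(metal.xyz)

    candidates: list[tuple[AtomSite, str, float]] = []
    if use_sym and model.cell is not None:
        for img in expand_symmetry(model, [metal], max_cut):
            candidates.append((img.atom, img.sym_label, img.distance))
    else:
        for a in model.atom_sites:
            if a is metal:
                continue
            d = float(np.linalg.norm(np.asarray(a.xyz) - m_xyz))
            if d <= max_cut:
                candidates.append((a, IDENTITY_SYM_LABEL, d))

    ligators: list[Ligator] = []
    for atom, sym_label, dist in candidates:
        if atom.element.upper() not in DONOR_ELEMENTS:
            continue
        if dist > metal_cutoff(el, atom.element, cutoffs) or dist < 1e-6:
            continue
        ligators.append(
            Ligator(atom=AtomRef.from_site(atom, sym_label), distance=dist,
                    xyz=tuple(atom.xyz))
        )
    ligators.sort(key=lambda l: (l.atom.auth_chain, l.atom.auth_seq, l.atom.atom_name,
                                 l.atom.alt_loc, l.atom.sym_label))

    center = CoordinationCenter(
        metal=AtomRef.from_site(metal), metal_xyz=tuple(metal.xyz), ligators=ligators
    )
    for i in range(len(ligators)):
        for j in range(i + 1, len(ligators)):
            ang = _angle_deg(m_xyz, np.asarray(ligators[i].xyz), np.asarray(ligators[j].xyz))
            center.angles.append((i, j, ang))
    return center


def find_metal_sites(model: StructureModel) -> list[AtomSite]:
    """All atom sites whose element is a supported metal and whose component
    is a metal ion or metal-bearing ligand (any non-polymer component)."""
    return [
        a for a in model.atom_sites
        if a.element.upper() in SUPPORTED_METALS
    ]


def write_struct_conn(linkages: Sequence[Linkage]) -> str:
    """Serialize linkages to the mmCIF ``_struct_conn`` category."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("linkages")
    if linkages:
        block.set_mmcif_category(
            "_struct_conn.",
            {
                "id": [f"{l.kind}{i + 1}" for i, l in enumerate(linkages)],
                "conn_type_id": [l.kind for l in linkages],
                "ptnr1_auth_comp_id": [l.partner1.comp_id for l in linkages],
                "ptnr1_auth_asym_id": [l.partner1.auth_chain for l in linkages],
                "ptnr1_auth_seq_id": [str(l.partner1.auth_seq) for l in linkages],
                "pdbx_ptnr1_PDB_ins_code": [l.partner1.ins_code or "?" for l in linkages],
                "ptnr1_label_atom_id": [l.partner1.atom_name for l in linkages],
                "pdbx_ptnr1_label_alt_id": [l.partner1.alt_loc or "?" for l in linkages],
                "ptnr1_symmetry": [l.partner1.sym_label for l in linkages],
                "ptnr2_auth_comp_id": [l.partner2.comp_id for l in linkages],
                "ptnr2_auth_asym_id": [l.partner2.auth_chain for l in linkages],
                "ptnr2_auth_seq_id": [str(l.partner2.auth_seq) for l in linkages],
                "pdbx_ptnr2_PDB_ins_code": [l.partner2.ins_code or "?" for l in linkages],
                "ptnr2_label_atom_id": [l.partner2.atom_name for l in linkages],
                "pdbx_ptnr2_label_alt_id": [l.partner2.alt_loc or "?" for l in linkages],
                "ptnr2_symmetry": [l.partner2.sym_label for l in linkages],
                "pdbx_dist_value": [f"{l.distance:.3f}" for l in linkages],
            },
        )
    return doc.as_string()


def _lig_label(l: Ligator) -> str:
    alt = l.atom.alt_loc or " "
    return (f"{l.atom.comp_id:>3s}{alt}{l.atom.auth_chain:>2s}"
            f"{l.atom.auth_seq:>4d}{l.atom.ins_code or ' '} {l.atom.atom_name:<4s}")


def write_remark620(centers: Sequence[CoordinationCenter]) -> str:
    """Fixed-column REMARK 620 text: one block per metal center listing the
    ligators and the lower-triangular matrix of pairwise angles."""
    lines: list[str] = []

    def put(text: str) -> None:
        lines.append(f"REMARK 620 {text}".rstrip())

    lines.append("REMARK 620")
    lines.append("REMARK 620 COORDINATION ANGLES FOR COORDINATED METAL CENTERS")
    for center in centers:
        lines.append("REMARK 620")
        m = center.metal
        put("COORDINATION ANGLES FOR:")
        put(f"M {m.comp_id:>3s} {m.auth_chain:>2s}{m.auth_seq:>4d}{m.ins_code or ' '} "
            f"{m.atom_name:<4s}")
        put("N RES CSSEQI ATOM")
        angle_of = {(i, j): ang for i, j, ang in center.angles}
        for j, lig in enumerate(center.ligators):
            row = f"{j + 1:>2d} {_lig_label(lig)}"
            for i in range(j):
                ang = angle_of[(i, j)]
                row += f"{ang:7.1f}"
            put(row)
    lines.append("REMARK 620")
    return "\n".join(lines) + "\n"


def parse_remark620(text: str) -> list[CoordinationCenter]:
    """Re-parse REMARK 620 blocks written by :func:`write_remark620` into
    centers carrying ligator references and the angle matrix (coordinates
    are not stored in the remark and come back as NaN)."""
    centers: list[CoordinationCenter] = []
    current: Optional[CoordinationCenter] = None
    expect_metal = False
    for line in text.splitlines():
        if not line.startswith("REMARK 620"):
            continue
        body = line[10:].strip()
        if body == "COORDINATION ANGLES FOR:":
            expect_metal = True
            continue
        if expect_metal and body.startswith("M "):
            parts = body[2:]
            comp_id = parts[0:3].strip()
            chain = parts[4:6].strip()
            seq = int(parts[6:10])
            ins = parts[10:11].strip()
            name = parts[12:16].strip()
            current = CoordinationCenter(
                metal=AtomRef(comp_id, chain, seq, ins, name),
                metal_xyz=(math.nan, math.nan, math.nan),
            )
            centers.append(current)
            expect_metal = False
            continue
        if current is not None and body[:2].strip().isdigit():
            idx = int(body[:2]) - 1
            rest = body[3:]
            comp_id = rest[0:3].strip()
            alt = rest[3:4].strip()
            chain = rest[4:6].strip()
            seq = int(rest[6:10])
            ins = rest[10:11].strip()
            name = rest[12:16].strip()
            angles_str = rest[16:]
            ref = AtomRef(comp_id, chain, seq, ins, name, alt)
            current.ligators.append(
                Ligator(atom=ref, distance=math.nan, xyz=(math.nan, math.nan, math.nan))
            )
            for i in range(idx):
                chunk = angles_str[i * 7:(i + 1) * 7].strip()
                if chunk:
                    current.angles.append((i, idx, float(chunk)))
    return centers


def write_conn_angle(centers: Sequence[CoordinationCenter]) -> str:
    """Serialize metal-center angles to mmCIF ``_pdbx_struct_conn_angle``,
    one row per ligator pair."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("conn_angles")
    rows = [(c, i, j, ang) for c in centers for i, j, ang in c.angles]
    if rows:
        def ref_cols(prefix: str, refs: list[AtomRef]) -> dict[str, list[str]]:
            return {
                f"{prefix}_auth_comp_id": [r.comp_id for r in refs],
                f"{prefix}_auth_asym_id": [r.auth_chain for r in refs],
                f"{prefix}_auth_seq_id": [str(r.auth_seq) for r in refs],
                f"{prefix}_label_atom_id": [r.atom_name for r in refs],
                f"{prefix}_label_alt_id": [r.alt_loc or "?" for r in refs],
                f"{prefix}_symmetry": [r.sym_label for r in refs],
            }

        cat: dict[str, list[str]] = {"id": [str(k + 1) for k in range(len(rows))]}
        cat.update(ref_cols("ptnr1", [c.ligators[i].atom for c, i, j, _ in rows]))
        cat.update(ref_cols("ptnr2", [c.metal for c, _, _, _ in rows]))
        cat.update(ref_cols("ptnr3", [c.ligators[j].atom for c, i, j, _ in rows]))
        cat["value"] = [f"{ang:.1f}" for _, _, _, ang in rows]
        block.set_mmcif_category("_pdbx_struct_conn_angle.", cat)
    return doc.as_string()


def parse_conn_angle(cif_text: str) -> list[tuple[AtomRef, AtomRef, AtomRef, float]]:
    """Rows of (ligator1, metal, ligator2, degrees) from the category written
    by :func:`write_conn_angle`."""
    doc = gemmi.cif.read_string(cif_text)
    if not len(doc):
        return []
    cat = doc[0].get_mmcif_category("_pdbx_struct_conn_angle.", raw=False)
    if not cat:
        return []
    n = len(cat["value"])

    def ref(prefix: str, i: int) -> AtomRef:
        alt = cat.get(f"{prefix}_label_alt_id", [""] * n)[i]
        return AtomRef(
            comp_id=cat[f"{prefix}_auth_comp_id"][i],
            auth_chain=cat[f"{prefix}_auth_asym_id"][i],
            auth_seq=int(cat[f"{prefix}_auth_seq_id"][i]),
            ins_code="",
            atom_name=cat[f"{prefix}_label_atom_id"][i],
            alt_loc="" if alt in (None, False, "?", ".") else alt,
            sym_label=cat.get(f"{prefix}_symmetry", [IDENTITY_SYM_LABEL] * n)[i],
        )

    return [(ref("ptnr1", i), ref("ptnr2", i), ref("ptnr3", i), float(cat["value"][i]))
            for i in range(n)]
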