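"""Deterministic synthetic fixtures for every input the toolkit consumes.

Everything here is generated programmatically: chemical component
definitions with chemically consistent three-dimensional geometry
(pyranose sugar, amino acid, aromatic ring, water), crystal scenes with
known contact lists, oligosaccharide rings, peptide chains, metal centers,
and per-residue RSR tables with a known expected density-fit Z-score.

Each scene comes with ground truth computed by an independent brute-force
path (explicit operator-by-lattice-shift enumeration through gemmi's cell
arithmetic), never by the annotation modules themselves, so the test suite
has a genuine oracle.  All randomness derives from one integer seed via a
counter scheme: adding a fixture never shifts existing ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .bird import PeptideLikeMolecule, SubLink, Subcomponent
from .ccd import AtomDef, BondDef, ChemCompDef, formula_from_atoms
from .structure import (
    AtomSite,
    CrystalCell,
    ObservedComponent,
    ResidueKey,
    StructureModel,
    symops_for,
)

__all__ = [
    "make_ccd_fixture",
    "fixture_dictionary",
    "observed_from_def",
    "make_structure_fixture",
    "StructureFixtureSpec",
    "GroundTruth",
    "contact_scene",
    "placed_contact_scene",
    "cyclodextrin_scene",
    "peptide_chain_scene",
    "metal_scene",
    "make_peptide_molecule",
    "make_rsr_fixture",
    "brute_force_contacts",
    "model_to_pdb",
    "model_to_mmcif",
]


def _rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, counter])


# ---------------------------------------------------------------------------
# small-geometry helpers

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping direction a onto direction b (Rodrigues)."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular axis
        axis = _unit(np.cross(a, [1.0, 0.3, 0.2]))
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


_TETRA = math.acos(-1.0 / 3.0)  # 109.471 deg


def _tetra_dirs(known: Sequence[np.ndarray], n: int) -> list[np.ndarray]:
    """Unit directions completing a tetrahedral arrangement around a center,
    given the unit directions of already-placed substituents."""
    known = [np.asarray(k, dtype=float) for k in known]
    if len(known) == 0:
        base = [
            np.array([1.0, 1.0, 1.0]),
            np.array([1.0, -1.0, -1.0]),
            np.array([-1.0, 1.0, -1.0]),
            np.array([-1.0, -1.0, 1.0]),
        ]
        return [_unit(b) for b in base[:n]]
    if len(known) == 1:
        u = _unit(known[0])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u, ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        p = _unit(np.cross(u, ref))
        q = np.cross(u, p)
        out = []
        for k in range(3):
            phi = 2 * math.pi * k / 3
            d = math.cos(_TETRA) * u + math.sin(_TETRA) * (math.cos(phi) * p + math.sin(phi) * q)
            out.append(_unit(d))
        return out[:n]
    if len(known) == 2:
        u1, u2 = _unit(known[0]), _unit(known[1])
        b = -_unit(u1 + u2)
        p = _unit(np.cross(u1, u2))
        alpha, beta = math.sqrt(1.0 / 3.0), math.sqrt(2.0 / 3.0)
        return [_unit(alpha * b + s * beta * p) for s in (1.0, -1.0)][:n]
    return [-_unit(sum(_unit(k) for k in known))][:n]


# ---------------------------------------------------------------------------
# component definitions

_CC = 1.52   # single-bond C-C, A
_CO = 1.42   # C-O
_CN = 1.46   # C-N
_CH = 1.09
_OH = 0.96
_NH = 1.01
_C_DOUB_O = 1.23
_PEPTIDE_CN = 1.33


def _glc_geometry() -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Chair-conformation pyranose with hydroxyls, analogous to
    alpha-D-glucose; O1 is the anomeric hydroxyl oxygen eliminated on
    glycosidic bond formation."""
    d = 0.25
    a = math.sqrt(_CC**2 - 4 * d * d) / (2 * math.sin(math.pi / 6))
    ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    pos: dict[str, np.ndarray] = {}
    for k, name in enumerate(ring_names):
        th = math.pi / 3 * k
        pos[name] = np.array([a * math.cos(th), a * math.sin(th), d * (-1) ** k])
    bonds: list[tuple[str, str]] = [
        (ring_names[k], ring_names[(k + 1) % 6]) for k in range(6)
    ]

    centroid = np.mean([pos[n] for n in ring_names], axis=0)
    for k, (carbon, ox) in enumerate(
        [("C1", "O1"), ("C2", "O2"), ("C3", "O3"), ("C4", "O4")]
    ):
        prev_n = ring_names[(k - 1) % 6]
        next_n = ring_names[(k + 1) % 6]
        c = pos[carbon]
        d1, d2 = _tetra_dirs([_unit(pos[prev_n] - c), _unit(pos[next_n] - c)], 2)
        # equatorial-ish hydroxyl: the direction pointing away from the ring
        outward = _unit(c - centroid)
        o_dir, h_dir = (d1, d2) if np.dot(d1, outward) >= np.dot(d2, outward) else (d2, d1)
        pos[ox] = c + _CO * o_dir
        pos[f"H{k + 1}"] = c + _CH * h_dir
        bonds += [(carbon, ox), (carbon, f"H{k + 1}")]
        ho = f"HO{k + 1}"
        pos[ho] = pos[ox] + _OH * _tetra_dirs([_unit(c - pos[ox])], 3)[0]
        bonds.append((ox, ho))

    c5 = pos["C5"]
    d1, d2 = _tetra_dirs([_unit(pos["C4"] - c5), _unit(pos["O5"] - c5)], 2)
    outward = _unit(c5 - centroid)
    c6_dir, h5_dir = (d1, d2) if np.dot(d1, outward) >= np.dot(d2, outward) else (d2, d1)
    pos["C6"] = c5 + _CC * c6_dir
    pos["H5"] = c5 + _CH * h5_dir
    bonds += [("C5", "C6"), ("C5", "H5")]
    dirs = _tetra_dirs([_unit(c5 - pos["C6"])], 3)
    pos["O6"] = pos["C6"] + _CO * dirs[0]
    pos["H61"] = pos["C6"] + _CH * dirs[1]
    pos["H62"] = pos["C6"] + _CH * dirs[2]
    bonds += [("C6", "O6"), ("C6", "H61"), ("C6", "H62")]
    pos["HO6"] = pos["O6"] + _OH * _tetra_dirs([_unit(pos["C6"] - pos["O6"])], 3)[0]
    bonds.append(("O6", "HO6"))
    return pos, bonds


def _ala_geometry() -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Free amino acid with carboxy-terminal leaving group (OXT/HXT) and
    amino leaving hydrogen (H2), analogous to alanine."""
    pos: dict[str, np.ndarray] = {"CA": np.zeros(3)}
    t = _tetra_dirs([], 4)
    pos["N"] = _CN * t[0]
    pos["C"] = _CC * t[1]
    pos["CB"] = 1.53 * t[2]
    pos["HA"] = _CH * t[3]
    bonds = [("N", "CA"), ("CA", "C"), ("CA", "CB"), ("CA", "HA")]

    c = pos["C"]
    d1, d2, _ = _tetra_dirs([_unit(pos["CA"] - c)], 3)
    pos["O"] = c + _C_DOUB_O * d1
    pos["OXT"] = c + 1.25 * d2
    bonds += [("C", "O"), ("C", "OXT")]
    pos["HXT"] = pos["OXT"] + _OH * _tetra_dirs([_unit(c - pos["OXT"])], 3)[0]
    bonds.append(("OXT", "HXT"))

    n = pos["N"]
    nd = _tetra_dirs([_unit(pos["CA"] - n)], 3)
    pos["H"] = n + _NH * nd[0]
    pos["H2"] = n + _NH * nd[1]
    bonds += [("N", "H"), ("N", "H2")]

    cb = pos["CB"]
    bd = _tetra_dirs([_unit(pos["CA"] - cb)], 3)
    for i, d in enumerate(bd, start=1):
        pos[f"HB{i}"] = cb + _CH * d
        bonds.append(("CB", f"HB{i}"))
    return pos, bonds


def _benzene_geometry() -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    pos: dict[str, np.ndarray] = {}
    bonds = []
    for k in range(6):
        th = math.pi / 3 * k
        d = np.array([math.cos(th), math.sin(th), 0.0])
        pos[f"C{k + 1}"] = 1.39 * d
        pos[f"H{k + 1}"] = 2.48 * d
        bonds.append((f"C{k + 1}", f"H{k + 1}"))
    for k in range(6):
        bonds.append((f"C{k + 1}", f"C{(k + 1) % 6 + 1}"))
    return pos, bonds


def _hoh_geometry() -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    ang = math.radians(104.5)
    pos = {
        "O": np.zeros(3),
        "H1": 0.96 * np.array([1.0, 0.0, 0.0]),
        "H2": 0.96 * np.array([math.cos(ang), math.sin(ang), 0.0]),
    }
    return pos, [("O", "H1"), ("O", "H2")]


_FIXTURE_KINDS = {
    "GLC": (_glc_geometry, "D-saccharide", {"O1"}, "alpha-pyranose sugar fixture"),
    "ALA": (_ala_geometry, "L-peptide linking", {"OXT", "HXT", "H2"}, "amino-acid fixture"),
    "BNZ": (_benzene_geometry, "non-polymer", set(), "aromatic ring fixture"),
    "HOH": (_hoh_geometry, "non-polymer", set(), "water fixture"),
}

_KIND_ALIASES = {
    "GLC-LIKE": "GLC", "AMINO-ACID": "ALA", "ALA-LIKE": "ALA",
    "BENZENE-LIKE": "BNZ", "BENZENE": "BNZ", "WATER": "HOH",
}


def make_ccd_fixture(kind: str, seed: int = 0, jitter: float = 0.01) -> ChemCompDef:
    """A chemically consistent synthetic component definition.

    Kinds: ``GLC`` (pyranose sugar with a leaving anomeric oxygen O1),
    ``ALA`` (amino acid with OXT/HXT/H2 leaving atoms), ``BNZ`` (aromatic
    six-ring), ``HOH`` (water).  The seed perturbs coordinates by a small
    jitter without changing the topology.
    """
    key = _KIND_ALIASES.get(kind.upper(), kind.upper())
    if key not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    geom_fn, comp_type, leaving, name = _FIXTURE_KINDS[key]
    pos, bonds = geom_fn()
    rng = _rng(seed, counter=hash(key) & 0xFFFF)
    atoms = []
    for atom_id, xyz in pos.items():
        element = "H" if atom_id.startswith("H") else atom_id[0]
        p = tuple(float(x) for x in (xyz + rng.normal(0.0, jitter, size=3)))
        atoms.append(
            AtomDef(
                atom_id=atom_id,
                element=element,
                leaving=atom_id in leaving,
                aromatic=(key == "BNZ" and element == "C"),
                ideal_xyz=p,
                model_xyz=p,
            )
        )
    bond_defs = []
    for a1, a2 in bonds:
        arom = key == "BNZ" and a1.startswith("C") and a2.startswith("C")
        doub = key == "ALA" and {a1, a2} == {"C", "O"}  # carbonyl
        order = "AROM" if arom else ("DOUB" if doub else "SING")
        bond_defs.append(BondDef(a1, a2, order=order, aromatic=arom))
    cdef = ChemCompDef(
        comp_id=key,
        name=name,
        comp_type=comp_type,
        pdbx_type="ATOMS" if key == "GLC" else ("ATOMP" if key == "ALA" else "HETAIN"),
        atoms=atoms,
        bonds=bond_defs,
        formula=formula_from_atoms(atoms),
        formula_weight=round(sum(gemmi.Element(a.element).weight for a in atoms), 3),
    )
    return cdef


def fixture_dictionary(seed: int = 0) -> list[ChemCompDef]:
    """The four-component dictionary used across the test surface."""
    return [make_ccd_fixture(k, seed) for k in ("GLC", "ALA", "BNZ", "HOH")]


def observed_from_def(
    cdef: ChemCompDef,
    comp_id: Optional[str] = None,
    auth_chain: str = "A",
    auth_seq: int = 1,
    include_hydrogens: bool = False,
    drop_atoms: Sequence[str] = (),
    rotation: Optional[np.ndarray] = None,
    translation: Sequence[float] = (0.0, 0.0, 0.0),
    serial_start: int = 1,
    is_polymer: bool = False,
) -> ObservedComponent:
    """Instantiate an observed component from a definition's model
    coordinates, optionally dropping atoms and applying a rigid motion —
    what an X-ray deposition of the compound would look like."""
    rot = np.eye(3) if rotation is None else rotation
    tr = np.asarray(translation, dtype=float)
    comp = ObservedComponent(
        comp_id=comp_id or cdef.comp_id,
        auth_chain=auth_chain,
        auth_seq=auth_seq,
        ins_code="",
        is_polymer_residue=is_polymer,
    )
    serial = serial_start
    for a in cdef.atoms:
        if a.atom_id in drop_atoms:
            continue
        if not include_hydrogens and a.is_hydrogen:
            continue
        xyz = rot @ np.asarray(a.model_xyz) + tr
        comp.atoms.append(
            AtomSite(
                serial=serial,
                atom_name=a.atom_id,
                alt_loc="",
                comp_id=comp.comp_id,
                auth_chain=auth_chain,
                auth_seq=auth_seq,
                ins_code="",
                xyz=tuple(float(x) for x in xyz),
                element=a.element,
            )
        )
        serial += 1
    return comp


# ---------------------------------------------------------------------------
# structure scenes with ground truth


@dataclass
class GroundTruth:
    """Independently computed expectations for a generated scene."""

    #: per ligand group: set of (residue_key, sym_label) within the cutoff
    contacts: dict[str, set[tuple[ResidueKey, str]]] = field(default_factory=dict)
    contact_cutoff: float = 3.7
    #: inter-component covalent pairs ((residue_key, atom), (residue_key, atom))
    links: list[tuple] = field(default_factory=list)
    peptide_bond_count: int = 0
    metal_angles: list[float] = field(default_factory=list)
    expected_lldf: Optional[float] = None


@dataclass
class StructureFixtureSpec:
    """Declarative description of a synthetic crystal scene."""

    space_group: str = "P 1"
    cell_lengths: tuple[float, float, float] = (30.0, 30.0, 30.0)
    cell_angles: tuple[float, float, float] = (90.0, 90.0, 90.0)
    n_residues: int = 5
    ligand_kind: Optional[str] = "BNZ"
    topology: str = "random"  # random | cyclodextrin | peptide | metal
    peptide_length: int = 5
    noise: float = 0.0
    contact_cutoff: float = 3.7


def _assemble_model(
    components: Sequence[ObservedComponent],
    cell: Optional[CrystalCell],
) -> StructureModel:
    model = StructureModel(cell=cell)
    for comp in components:
        model.components.append(comp)
        model.atom_sites.extend(comp.atoms)
    chains: dict[str, list[ObservedComponent]] = {}
    for comp in components:
        if comp.is_polymer_residue:
            chains.setdefault(comp.auth_chain, []).append(comp)
    for name, comps in chains.items():
        comps.sort(key=lambda c: (c.auth_seq, c.ins_code))
        model.chains[name] = comps
    return model


def brute_force_contacts(
    model: StructureModel,
    ligand_atoms: Sequence[AtomSite],
    cutoff: float,
    own_keys: Optional[set[ResidueKey]] = None,
) -> set[tuple[ResidueKey, str]]:
    """Reference contact computation: enumerate every operator and every
    lattice shift in (-2..2)^3 explicitly, through gemmi's cell arithmetic,
    and keep residues with any image atom within the cutoff of any ligand
    atom.  The shift range is exhaustive for cutoffs smaller than the cell
    edges even when an operator moves coordinates outside the unit box.
    Identity images of the ligand's own residues are excluded."""
    assert model.cell is not None
    cell = gemmi.UnitCell(
        model.cell.a, model.cell.b, model.cell.c,
        model.cell.alpha, model.cell.beta, model.cell.gamma,
    )
    sg = gemmi.find_spacegroup_by_name(model.cell.space_group)
    ops = list(sg.operations())
    den = float(gemmi.Op.DEN)
    own = own_keys or {a.residue_key for a in ligand_atoms}
    lig = np.array([a.xyz for a in ligand_atoms])
    lig_ids = {id(a) for a in ligand_atoms}

    found: set[tuple[ResidueKey, str]] = set()
    for atom in model.atom_sites:
        f = cell.fractionalize(gemmi.Position(*atom.xyz))
        fv = np.array([f.x, f.y, f.z])
        for op_idx, op in enumerate(ops, start=1):
            rot = np.array(op.rot, dtype=float) / den
            tran = np.array(op.tran, dtype=float) / den
            base = rot @ fv + tran
            for sh in itertools.product((-2, -1, 0, 1, 2), repeat=3):
                identity = op_idx == 1 and sh == (0, 0, 0)
                if identity and (id(atom) in lig_ids or atom.residue_key in own):
                    continue
                fr = base + np.array(sh, dtype=float)
                p = cell.orthogonalize(gemmi.Fractional(*fr))
                pv = np.array([p.x, p.y, p.z])
                if np.min(np.linalg.norm(lig - pv, axis=1)) <= cutoff:
                    label = f"{op_idx}_{5 + sh[0]}{5 + sh[1]}{5 + sh[2]}"
                    found.add((atom.residue_key, label))
    return found


def _place_rigid(
    comp: ObservedComponent, rot: np.ndarray, target: np.ndarray
) -> ObservedComponent:
    coords = np.array([a.xyz for a in comp.atoms])
    center = coords.mean(axis=0)
    new = (coords - center) @ rot.T + target
    for a, xyz in zip(comp.atoms, new):
        a.xyz = tuple(float(x) for x in xyz)
    return comp


def contact_scene(
    seed: int,
    space_group: str = "P 1",
    n_residues: int = 6,
    cutoff: float = 3.7,
) -> tuple[StructureModel, GroundTruth]:
    """A randomized crystal scene for exercising the contact engine: one
    rigid ligand and a handful of residues scattered in the asymmetric
    unit, small enough that symmetry images genuinely enter the 3.7 A
    shell.  Ground truth from :func:`brute_force_contacts`."""
    rng = _rng(seed, counter=101)
    lengths = tuple(float(x) for x in rng.uniform(16.0, 24.0, size=3))
    cell = CrystalCell(*lengths, 90.0, 90.0, 90.0, space_group=space_group)

    ala = make_ccd_fixture("ALA", seed=0)
    bnz = make_ccd_fixture("BNZ", seed=0)

    comps: list[ObservedComponent] = []
    serial = 1
    for i in range(n_residues):
        comp = observed_from_def(
            ala, auth_chain="A", auth_seq=i + 1, serial_start=serial, is_polymer=True
        )
        serial += len(comp.atoms)
        target = np.array(lengths) * rng.uniform(0.05, 0.95, size=3)
        _place_rigid(comp, _random_rotation(rng), target)
        comps.append(comp)

    lig = observed_from_def(bnz, auth_chain="A", auth_seq=201, serial_start=serial)
    target = np.array(lengths) * rng.uniform(0.05, 0.95, size=3)
    _place_rigid(lig, _random_rotation(rng), target)
    comps.append(lig)

    model = _assemble_model(comps, cell)
    truth = GroundTruth(contact_cutoff=cutoff)
    truth.contacts["ligand"] = brute_force_contacts(model, lig.atoms, cutoff)
    return model, truth


def placed_contact_scene(
    close: Sequence[float] = (3.0, 3.2, 3.4, 3.6),
    far: Sequence[float] = (4.0, 4.5),
    seed: int = 0,
) -> tuple[StructureModel, GroundTruth]:
    """A big-P1 scene with residues placed at controlled minimum distances
    from the ligand, so the expected contact list is known by construction."""
    rng = _rng(seed, counter=102)
    cell = CrystalCell(80.0, 80.0, 80.0, 90.0, 90.0, 90.0, space_group="P 1")
    bnz = make_ccd_fixture("BNZ", seed=0)
    ala = make_ccd_fixture("ALA", seed=0)
    center = np.array([40.0, 40.0, 40.0])
    lig = observed_from_def(bnz, auth_chain="A", auth_seq=301, serial_start=1)
    _place_rigid(lig, np.eye(3), center)
    lig_xyz = np.array([a.xyz for a in lig.atoms])

    comps = [lig]
    serial = 1 + len(lig.atoms)
    expected: set[tuple[ResidueKey, str]] = set()
    for i, dist in enumerate(list(close) + list(far)):
        direction = _unit(rng.normal(size=3))
        # nearest ligand atom along this direction
        proj = lig_xyz @ direction
        anchor = lig_xyz[int(np.argmax(proj))]
        comp = observed_from_def(
            ala, auth_chain="B", auth_seq=i + 1, serial_start=serial, is_polymer=True
        )
        serial += len(comp.atoms)
        coords = np.array([a.xyz for a in comp.atoms])
        # put atom N exactly at `dist` from the anchor, rest of the residue beyond
        n_idx = next(k for k, a in enumerate(comp.atoms) if a.atom_name == "N")
        spread = coords - coords[n_idx]
        rot = _rotation_between(spread.mean(axis=0) + 1e-9, direction)
        coords = spread @ rot.T + anchor + dist * direction
        for a, xyz in zip(comp.atoms, coords):
            a.xyz = tuple(float(x) for x in xyz)
        comps.append(comp)
        if dist <= 3.7:
            expected.add((comp.residue_key, "1_555"))

    model = _assemble_model(comps, cell)
    truth = GroundTruth(contact_cutoff=3.7)
    truth.contacts["ligand"] = expected
    return model, truth


def cyclodextrin_scene(seed: int = 0, n_units: int = 7, with_protein: bool = True):
    """A macrocycle of glucose units joined by glycosidic O4->C1 bonds at
    1.42 A, emulating beta-cyclodextrin: every unit has lost its leaving O1,
    adjacent units share exactly one covalent-range atom pair, and the whole
    ring is one grouped ligand.  Returns (model, ground_truth, group_map)."""
    glc = make_ccd_fixture("GLC", seed=0)
    pos = {a.atom_id: np.asarray(a.model_xyz) for a in glc.atoms}
    u = pos["O4"] - pos["C1"]
    d = float(np.linalg.norm(u))
    s = d + 1.42
    radius = s / (2.0 * math.sin(math.pi / n_units))
    cell = CrystalCell(90.0, 90.0, 90.0, 90.0, 90.0, 90.0, space_group="P 1")
    center = np.array([45.0, 45.0, 45.0])

    verts = [
        center + radius * np.array([math.cos(2 * math.pi * i / n_units),
                                    math.sin(2 * math.pi * i / n_units), 0.0])
        for i in range(n_units)
    ]

    def build_ring(roll_deg: float) -> list[ObservedComponent]:
        units = []
        serial = 1
        for i in range(n_units):
            t = _unit(verts[(i + 1) % n_units] - verts[i])
            rot = _rotation_between(u, t)
            # tilt each sugar ring out of the macrocycle plane to keep
            # neighbors clear of each other except at the glycosidic bond
            rot = _axis_rotation(t, math.radians(roll_deg)) @ rot
            comp = observed_from_def(
                glc, auth_chain="C", auth_seq=i + 1, serial_start=serial,
                drop_atoms=("O1",),
            )
            serial += len(comp.atoms)
            comp.group_id = "CD1"
            coords = np.array([a.xyz for a in comp.atoms])
            c1 = coords[[a.atom_name for a in comp.atoms].index("C1")]
            coords = (coords - c1) @ rot.T + verts[i]
            for a, xyz in zip(comp.atoms, coords):
                a.xyz = tuple(float(x) for x in xyz)
            units.append(comp)
        return units

    def ring_is_clean(units: list[ObservedComponent]) -> bool:
        # exactly one covalent-range inter-unit pair per adjacent couple
        # (the O4->C1 glycosidic bond), none between non-adjacent units
        for i in range(n_units):
            for j in range(i + 1, n_units):
                close = []
                for a in units[i].atoms:
                    for b in units[j].atoms:
                        reach = (gemmi.Element(a.element).covalent_r
                                 + gemmi.Element(b.element).covalent_r + 0.45)
                        if np.linalg.norm(np.subtract(a.xyz, b.xyz)) <= reach:
                            close.append((a.atom_name, b.atom_name))
                adjacent = j - i == 1 or (i == 0 and j == n_units - 1)
                want = [("O4", "C1")] if j - i == 1 else (
                    [("C1", "O4")] if adjacent else [])
                if sorted(close) != sorted(want):
                    return False
        return True

    comps: list[ObservedComponent] = []
    for roll in range(20, 90, 5):  # deterministic scan; first clean geometry wins
        candidate = build_ring(float(roll))
        if ring_is_clean(candidate):
            comps = candidate
            break
    if not comps:
        raise RuntimeError("no clash-free macrocycle orientation found")

    serial = 1 + sum(len(c.atoms) for c in comps)
    if with_protein:
        ala = make_ccd_fixture("ALA", seed=0)
        rng = _rng(seed, counter=103)
        sugar_xyz = np.array([a.xyz for c in comps for a in c.atoms])
        for j in range(3):
            th = 2 * math.pi * j / 3 + 0.3
            direction = np.array([math.cos(th), math.sin(th), 0.0])
            proj = sugar_xyz @ direction
            anchor = sugar_xyz[int(np.argmax(proj))]
            comp = observed_from_def(
                ala, auth_chain="A", auth_seq=j + 1, serial_start=serial, is_polymer=True
            )
            serial += len(comp.atoms)
            coords = np.array([a.xyz for a in comp.atoms])
            n_idx = next(k for k, a in enumerate(comp.atoms) if a.atom_name == "N")
            spread = coords - coords[n_idx]
            rot = _rotation_between(spread.mean(axis=0) + 1e-9, direction)
            coords = spread @ rot.T + anchor + 3.2 * direction
            for a, xyz in zip(comp.atoms, coords):
                a.xyz = tuple(float(x) for x in xyz)
            comps.append(comp)

    model = _assemble_model(comps, cell)
    truth = GroundTruth()
    keys = [c.residue_key for c in comps[:n_units]]
    for i in range(n_units):
        truth.links.append(
            ((keys[i], "O4"), (keys[(i + 1) % n_units], "C1"))
        )
    group_map = {k: "CD1" for k in keys}
    return model, truth, group_map


def peptide_chain_scene(
    k: int, seed: int = 0, cell_edge: float = 60.0
) -> tuple[StructureModel, GroundTruth]:
    """A linear chain of k amino-acid components joined by 1.33 A C-N
    bonds (OXT/HXT of every residue but the last eliminated), placed in a
    large P1 cell.  Ground truth: k-1 peptide bonds."""
    ala = make_ccd_fixture("ALA", seed=0)
    n_pos = np.asarray(ala.atom("N").model_xyz)
    c_pos = np.asarray(ala.atom("C").model_xyz)
    step = (c_pos - n_pos) + _PEPTIDE_CN * _unit(c_pos - n_pos)

    cell = CrystalCell(cell_edge, cell_edge, cell_edge, 90, 90, 90, space_group="P 1")
    offset = np.array([cell_edge / 4] * 3)
    comps = []
    serial = 1
    for i in range(k):
        drop = ("OXT",) if i < k - 1 else ()
        comp = observed_from_def(
            ala, auth_chain="A", auth_seq=i + 1, serial_start=serial,
            drop_atoms=drop, is_polymer=True,
        )
        serial += len(comp.atoms)
        shift = offset + i * step
        for a in comp.atoms:
            a.xyz = tuple(float(x) for x in (np.asarray(a.xyz) + shift))
        comps.append(comp)
    model = _assemble_model(comps, cell)
    truth = GroundTruth(peptide_bond_count=max(0, k - 1))
    return model, truth


_TETRAHEDRON_DIRS = [
    np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0),
    np.array([1.0, -1.0, -1.0]) / math.sqrt(3.0),
    np.array([-1.0, 1.0, -1.0]) / math.sqrt(3.0),
    np.array([-1.0, -1.0, 1.0]) / math.sqrt(3.0),
]


def metal_scene(
    kind: str = "tetrahedral", seed: int = 0, metal: str = "ZN", bond: float = 2.1
) -> tuple[StructureModel, GroundTruth]:
    """A metal ion with ligating carboxylate oxygens at exact geometry:
    ``tetrahedral`` (four ligators, all angles arccos(-1/3)) or ``linear``
    (two ligators at 180 degrees).  Ground truth lists the expected angles.
    """
    cell = CrystalCell(50.0, 50.0, 50.0, 90, 90, 90, space_group="P 1")
    center = np.array([25.0, 25.0, 25.0])
    dirs = _TETRAHEDRON_DIRS if kind == "tetrahedral" else [
        np.array([1.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0])
    ]
    comps = []
    zn = ObservedComponent(comp_id=metal, auth_chain="A", auth_seq=500, ins_code="")
    zn.atoms.append(
        AtomSite(serial=1, atom_name=metal, alt_loc="", comp_id=metal,
                 auth_chain="A", auth_seq=500, ins_code="",
                 xyz=tuple(center), element=metal.capitalize())
    )
    comps.append(zn)
    serial = 2
    for i, d in enumerate(dirs):
        res = ObservedComponent(comp_id="GLU", auth_chain="B", auth_seq=100 + i,
                                ins_code="", is_polymer_residue=True)
        oe = center + bond * d
        cd = center + (bond + 1.25) * d
        res.atoms.append(AtomSite(serial=serial, atom_name="OE1", alt_loc="",
                                  comp_id="GLU", auth_chain="B", auth_seq=100 + i,
                                  ins_code="", xyz=tuple(oe), element="O"))
        res.atoms.append(AtomSite(serial=serial + 1, atom_name="CD", alt_loc="",
                                  comp_id="GLU", auth_chain="B", auth_seq=100 + i,
                                  ins_code="", xyz=tuple(cd), element="C"))
        serial += 2
        comps.append(res)
    model = _assemble_model(comps, cell)
    truth = GroundTruth()
    if kind == "tetrahedral":
        truth.metal_angles = [math.degrees(_TETRA)] * 6
    else:
        truth.metal_angles = [180.0]
    return model, truth


def make_structure_fixture(
    spec: StructureFixtureSpec, seed: int = 0
) -> tuple[StructureModel, GroundTruth]:
    """Dispatch a declarative scene description to the concrete builders.

    All randomness comes from the seed; regenerating with the same spec and
    seed is bit-identical."""
    if spec.topology == "random":
        return contact_scene(seed, spec.space_group, spec.n_residues, spec.contact_cutoff)
    if spec.topology == "cyclodextrin":
        model, truth, _ = cyclodextrin_scene(seed)
        return model, truth
    if spec.topology == "peptide":
        return peptide_chain_scene(spec.peptide_length, seed)
    if spec.topology == "metal":
        return metal_scene("tetrahedral", seed)
    raise ValueError(f"unknown topology {spec.topology!r}")


# ---------------------------------------------------------------------------
# peptide-like molecules for the representation rules


def make_peptide_molecule(
    k: int,
    cyclic: bool = False,
    n_sugars: int = 0,
    acyl: bool = False,
    ester_junctions: Sequence[int] = (),
    warhead: bool = False,
    branch_at: Optional[int] = None,
    branch_length: int = 0,
) -> PeptideLikeMolecule:
    """Topology-level peptide-like molecule built from fixture definitions.

    ``k`` amino-acid subcomponents joined C(i)->N(i+1); selected junctions
    can be turned into ester (C-O) links; sugars attach to the first
    residue's O, an acyl chain to the first residue's N; ``warhead`` appends
    a nitrogen-free ketone fragment C-C-bonded to the last residue; a branch
    adds a side chain of additional residues peptide-bonded onto residue
    ``branch_at``."""
    ala = make_ccd_fixture("ALA", seed=0)
    glc = make_ccd_fixture("GLC", seed=0)
    subs = [Subcomponent(key=f"A{i + 1}", comp_id="ALA", definition=ala) for i in range(k)]
    links: list[SubLink] = []
    for i in range(k - 1):
        if i in ester_junctions:
            links.append(SubLink(f"A{i + 1}", "C", f"A{i + 2}", "OXT"))
        else:
            links.append(SubLink(f"A{i + 1}", "C", f"A{i + 2}", "N"))
    if cyclic and k > 2:
        links.append(SubLink(f"A{k}", "C", "A1", "N"))

    for j in range(n_sugars):
        key = f"S{j + 1}"
        subs.append(Subcomponent(key=key, comp_id="GLC", definition=glc))
        links.append(SubLink(key, "C1", "A1", "OXT" if not cyclic else "CB"))

    if acyl:
        fat = _fatty_acid_def()
        subs.append(Subcomponent(key="L1", comp_id="FAT", definition=fat))
        links.append(SubLink("L1", "C1", "A1", "N"))

    if warhead:
        ket = _warhead_def()
        subs.append(Subcomponent(key="W1", comp_id="KET", definition=ket))
        links.append(SubLink(f"A{k}", "C", "W1", "C1"))

    if branch_at is not None and branch_length > 0:
        prev = f"A{branch_at}"
        for j in range(branch_length):
            key = f"B{j + 1}"
            subs.append(Subcomponent(key=key, comp_id="ALA", definition=ala))
            links.append(SubLink(prev, "C" if j else "CB", key, "N"))
            prev = key
        # attach the branch through a peptide-like C->N junction at its root
        links[-branch_length] = SubLink(f"A{branch_at}", "C", "B1", "N")
    return PeptideLikeMolecule(subcomponents=subs, links=links)


def _fatty_acid_def() -> ChemCompDef:
    """An eight-carbon acyl chain with a carbonyl head: the fatty-acid
    attachment used by lipopeptide fixtures."""
    atoms = [AtomDef(atom_id="C1", element="C"), AtomDef(atom_id="O1", element="O")]
    bonds = [BondDef("C1", "O1", order="DOUB")]
    for i in range(2, 9):
        atoms.append(AtomDef(atom_id=f"C{i}", element="C"))
        bonds.append(BondDef(f"C{i - 1}", f"C{i}"))
    x = 0.0
    for a in atoms:
        a.model_xyz = (x, 0.0, 0.0)
        x += 1.5
    return ChemCompDef(comp_id="FAT", name="acyl chain fixture", atoms=atoms, bonds=bonds,
                       formula=formula_from_atoms(atoms))


def _warhead_def() -> ChemCompDef:
    """A nitrogen-free ketone fragment, standing in for an electrophilic
    warhead that caps a peptide without forming a peptide bond."""
    atoms = [
        AtomDef(atom_id="C1", element="C", model_xyz=(0.0, 0.0, 0.0)),
        AtomDef(atom_id="O1", element="O", model_xyz=(0.0, 1.23, 0.0)),
        AtomDef(atom_id="C2", element="C", model_xyz=(1.5, 0.0, 0.0)),
        AtomDef(atom_id="CL1", element="Cl", model_xyz=(2.4, 1.2, 0.0)),
    ]
    bonds = [BondDef("C1", "O1", order="DOUB"), BondDef("C1", "C2"), BondDef("C2", "CL1")]
    return ChemCompDef(comp_id="KET", name="warhead fixture", atoms=atoms, bonds=bonds,
                       formula=formula_from_atoms(atoms))


# ---------------------------------------------------------------------------
# RSR tables


def make_rsr_fixture(
    model: StructureModel,
    base: float = 0.12,
    ligand_offset: float = 0.2,
    noise_sigma: float = 0.02,
    seed: int = 0,
):
    """Per-residue RSR table emulating the statistical structure the LLDF
    assumes: polymer-residue RSR ~ Normal(base, sigma), every ligand at
    base + offset, so the expected Z-score is offset/sigma.

    Returns (RsrTable, expected_lldf).  sigma = 0 produces a degenerate
    table (all neighbors equal), exercising the undefined-score error path.
    """
    import pandas as pd

    from .validation import RsrTable

    rng = _rng(seed, counter=104)
    rows = []
    for comp in model.components:
        if comp.is_polymer_residue:
            val = base + (rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0)
            val = max(val, 1e-4)
        elif comp.is_water:
            continue
        else:
            val = base + ligand_offset
        rows.append(
            {"chain": comp.auth_chain, "seq": comp.auth_seq,
             "ins": comp.ins_code or ".", "comp_id": comp.comp_id, "rsr": round(val, 6)}
        )
    frame = pd.DataFrame(rows, columns=list(RsrTable.COLUMNS))
    expected = (ligand_offset / noise_sigma) if noise_sigma > 0 else None
    return RsrTable(frame), expected


# ---------------------------------------------------------------------------
# writers


def model_to_pdb(model: StructureModel) -> str:
    """Serialize a fixture model to PDB text (CRYST1 + ATOM/HETATM)."""
    lines = []
    if model.cell is not None:
        c = model.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {c.space_group:<11s}"
        )
    serial = 0
    for comp in model.components:
        rec = "ATOM  " if comp.is_polymer_residue else "HETATM"
        for a in comp.atoms:
            serial += 1
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            lines.append(
                f"{rec}{serial:5d} {name:<4s}{a.alt_loc or ' '}{a.comp_id:>3s} "
                f"{a.auth_chain[:1]}{a.auth_seq:4d}{a.ins_code or ' '}   "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def model_to_mmcif(model: StructureModel, entry_id: str = "FIXT") -> str:
    """Serialize a fixture model to PDBx/mmCIF text."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(entry_id)
    if model.cell is not None:
        c = model.cell
        block.set_mmcif_category(
            "_cell.",
            {"entry_id": [entry_id], "length_a": [f"{c.a:.3f}"],
             "length_b": [f"{c.b:.3f}"], "length_c": [f"{c.c:.3f}"],
             "angle_alpha": [f"{c.alpha:.2f}"], "angle_beta": [f"{c.beta:.2f}"],
             "angle_gamma": [f"{c.gamma:.2f}"]},
            raw=True,
        )
        block.set_mmcif_category(
            "_symmetry.",
            {"entry_id": [entry_id], "space_group_name_H-M": [f"'{c.space_group}'"]},
            raw=True,
        )
    cat: dict[str, list[str]] = {k: [] for k in (
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_seq_id", "auth_seq_id",
        "auth_asym_id", "auth_comp_id", "pdbx_PDB_ins_code",
        "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
        "pdbx_PDB_model_num",
    )}
    serial = 0
    for comp in model.components:
        group = "ATOM" if comp.is_polymer_residue else "HETATM"
        for a in comp.atoms:
            serial += 1
            cat["group_PDB"].append(group)
            cat["id"].append(str(serial))
            cat["type_symbol"].append(a.element.upper())
            cat["label_atom_id"].append(f'"{a.atom_name}"' if "'" in a.atom_name else a.atom_name)
            cat["label_alt_id"].append(a.alt_loc or ".")
            cat["label_comp_id"].append(a.comp_id)
            cat["label_asym_id"].append(a.auth_chain)
            cat["label_seq_id"].append(str(a.auth_seq))
            cat["auth_seq_id"].append(str(a.auth_seq))
            cat["auth_asym_id"].append(a.auth_chain)
            cat["auth_comp_id"].append(a.comp_id)
            cat["pdbx_PDB_ins_code"].append(a.ins_code or "?")
            cat["Cartn_x"].append(f"{a.xyz[0]:.3f}")
            cat["Cartn_y"].append(f"{a.xyz[1]:.3f}")
            cat["Cartn_z"].append(f"{a.xyz[2]:.3f}")
            cat["occupancy"].append(f"{a.occupancy:.2f}")
            cat["B_iso_or_equiv"].append(f"{a.b_factor:.2f}")
            cat["pdbx_PDB_model_num"].append(str(a.model_num))
    block.set_mmcif_category("_atom_site.", cat, raw=True)
    return doc.as_string()
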