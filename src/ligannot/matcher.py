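"""Identification of observed components against the dictionary.

An observed small molecule carries only element symbols and coordinates
(usually without hydrogens, and sometimes with leaving atoms eliminated by
covalent attachment).  Identification proceeds by perceiving bonds from
interatomic distances, matching the resulting element-labeled graph against
dictionary definitions — tolerant of absent hydrogens, leaving atoms and a
bounded amount of disorder — and then renaming the observed atoms to the
dictionary nomenclature.  Molecules new to the dictionary get a draft
definition built from the observation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import gemmi
import networkx as nx
import numpy as np

from .ccd import (
    AtomDef,
    BondDef,
    ChemCompDef,
    component_graph,
    formula_from_atoms,
)
from .structure import AtomSite, ObservedComponent

__all__ = [
    "ComponentMatch",
    "MatcherError",
    "covalent_radius",
    "perceive_bonds",
    "observed_graph",
    "match_component",
    "identify_component",
    "rename_atoms",
    "build_new_definition",
    "signed_volume",
    "BOND_TOLERANCE",
]

#: distance slack added to the sum of covalent radii when perceiving bonds.
#: Accepts stretched covalent bonds while rejecting hydrogen-bond contacts
#: (heavy-heavy >= ~2.4 A).
BOND_TOLERANCE = 0.45

#: fraction of dictionary heavy atoms that may be missing for reasons other
#: than leaving-atom elimination (crystallographic disorder).
DEFAULT_MISSING_BUDGET = 0.2


class MatcherError(ValueError):
    pass


def covalent_radius(element: str) -> float:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise MatcherError(f"unknown element symbol {element!r}")
    return el.covalent_r


def _altloc_compatible(a: AtomSite, b: AtomSite) -> bool:
    return a.alt_loc == b.alt_loc or not a.alt_loc or not b.alt_loc


def perceive_bonds(
    component: ObservedComponent, tolerance: float = BOND_TOLERANCE
) -> list[tuple[int, int]]:
    """Bond perception by covalent radii: atoms i<j (indices into
    ``component.atoms``) are bonded iff their distance is at most
    r_cov(i) + r_cov(j) + tolerance and their altlocs are compatible."""
    atoms = component.atoms
    if not atoms:
        raise MatcherError("bond perception needs at least one atom")
    radii = [covalent_radius(a.element) for a in atoms]
    coords = np.array([a.xyz for a in atoms])
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if not _altloc_compatible(atoms[i], atoms[j]):
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= radii[i] + radii[j] + tolerance:
                bonds.append((i, j))
    return bonds


def observed_graph(
    component: ObservedComponent,
    bonds: Optional[Sequence[tuple[int, int]]] = None,
    heavy_only: bool = True,
) -> nx.Graph:
    """Element-labeled graph of an observed component, nodes keyed by atom
    index.  Hydrogens are dropped by default: X-ray depositions routinely
    omit them and matching never requires them."""
    if bonds is None:
        bonds = perceive_bonds(component)
    g = nx.Graph()
    for idx, atom in enumerate(component.atoms):
        if heavy_only and atom.is_hydrogen:
            continue
        g.add_node(idx, element=atom.element)
    for i, j in bonds:
        if g.has_node(i) and g.has_node(j):
            g.add_edge(i, j)
    return g


@dataclass
class ComponentMatch:
    comp_id: str
    #: observed atom index -> dictionary atom_id
    atom_map: dict[int, str]
    #: dictionary atoms with no observed partner, flagged leaving/hydrogen/other
    missing_atoms: dict[str, str] = field(default_factory=dict)
    #: observed heavy-atom indices left unmapped
    extra_atoms: list[int] = field(default_factory=list)
    rmsd_after_fit: float = math.nan

    @property
    def exact(self) -> bool:
        return not self.extra_atoms and all(
            kind != "other" for kind in self.missing_atoms.values()
        )

    @property
    def n_missing_other(self) -> int:
        return sum(1 for kind in self.missing_atoms.values() if kind == "other")


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD of p onto q after optimal rigid superposition."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff * diff).sum() / len(p)))


def _match_rmsd(component: ObservedComponent, cdef: ChemCompDef, mapping: dict[int, str]) -> float:
    obs, ref = [], []
    for idx, atom_id in mapping.items():
        a = cdef.atom(atom_id)
        ref_xyz = a.model_xyz if a.model_xyz is not None else a.ideal_xyz
        if ref_xyz is None:
            continue
        obs.append(component.atoms[idx].xyz)
        ref.append(ref_xyz)
    if len(obs) < 3:
        return math.nan
    return _kabsch_rmsd(np.array(obs), np.array(ref))


def _mapping_key(component, cdef, mapping) -> tuple:
    dict_heavy = {a.atom_id for a in cdef.heavy_atoms()}
    mapped = set(mapping.values())
    missing = dict_heavy - mapped
    n_non_leaving = sum(1 for aid in missing if not cdef.atom(aid).leaving)
    rmsd = _match_rmsd(component, cdef, mapping)
    lex = tuple(sorted(mapping.items()))
    return (n_non_leaving, rmsd if not math.isnan(rmsd) else math.inf, lex)


def match_component(
    component: ObservedComponent,
    cdef: ChemCompDef,
    bonds: Optional[Sequence[tuple[int, int]]] = None,
    missing_budget: float = DEFAULT_MISSING_BUDGET,
) -> Optional[ComponentMatch]:
    """Match an observed component against one dictionary definition.

    The observed heavy-atom graph must embed into the dictionary heavy-atom
    graph with elements agreeing on every mapped pair; dictionary hydrogens
    and leaving atoms may be absent from the observation, and up to
    ``missing_budget`` (fraction of heavy atoms) of other dictionary atoms
    may be missing to accommodate disorder.  Bond orders are not compared —
    they are unobservable from X-ray coordinates.  Ties are broken by fewest
    missing non-leaving atoms, then lowest RMSD after superposition, then
    the lexicographically smallest atom map.
    """
    obs_g = observed_graph(component, bonds=bonds)
    if obs_g.number_of_nodes() == 0:
        return None
    dict_g = component_graph(cdef, include_hydrogens=False, include_leaving=True)
    n_dict = dict_g.number_of_nodes()
    if obs_g.number_of_nodes() > n_dict:
        return None

    budget = math.ceil(missing_budget * n_dict)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        dict_g,
        obs_g,
        node_match=lambda d1, d2: d1["element"] == d2["element"],
    )

    best = None
    best_key = None
    seen: set[frozenset] = set()
    for iso in matcher.subgraph_monomorphisms_iter():
        # iso maps dictionary atom_id -> observed index
        mapping = {obs_idx: atom_id for atom_id, obs_idx in iso.items()}
        sig = frozenset(mapping.items())
        if sig in seen:
            continue
        seen.add(sig)
        missing = {
            a.atom_id: ("leaving" if a.leaving else "other")
            for a in cdef.heavy_atoms()
            if a.atom_id not in iso
        }
        if sum(1 for k in missing.values() if k == "other") > budget:
            continue
        key = _mapping_key(component, cdef, mapping)
        if best_key is None or key < best_key:
            best_key = key
            best = (mapping, missing)

    if best is None:
        return None
    mapping, missing = best
    for a in cdef.atoms:
        if a.is_hydrogen:
            missing.setdefault(a.atom_id, "hydrogen")
    heavy_idx = set(obs_g.nodes)
    extra = sorted(heavy_idx - set(mapping))
    return ComponentMatch(
        comp_id=cdef.comp_id,
        atom_map=mapping,
        missing_atoms=missing,
        extra_atoms=extra,
        rmsd_after_fit=_match_rmsd(component, cdef, mapping),
    )


def _element_counts(atoms: Iterable) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a in atoms:
        if a.is_hydrogen:
            continue
        counts[a.element] = counts.get(a.element, 0) + 1
    return counts


def _formula_compatible(
    component: ObservedComponent, cdef: ChemCompDef, missing_budget: float
) -> bool:
    obs = _element_counts(component.atoms)
    ref = _element_counts(cdef.atoms)
    leaving = _element_counts([a for a in cdef.atoms if a.leaving])
    n_ref = sum(ref.values())
    budget = math.ceil(missing_budget * n_ref)
    deficit_other = 0
    for el, n in obs.items():
        if n > ref.get(el, 0):
            return False
    for el, n in ref.items():
        deficit = n - obs.get(el, 0)
        deficit_other += max(0, deficit - leaving.get(el, 0))
    return deficit_other <= budget


def identify_component(
    component: ObservedComponent,
    dictionary: Sequence[ChemCompDef],
    missing_budget: float = DEFAULT_MISSING_BUDGET,
) -> list[ComponentMatch]:
    """Rank dictionary candidates for an observed component, best first.

    Candidates are pre-filtered by heavy-atom element multiset (allowing
    leaving-atom deficits and the disorder budget) before graph matching.
    An empty result means the molecule is new to the dictionary.
    """
    if not dictionary:
        raise MatcherError("empty dictionary")
    bonds = perceive_bonds(component) if component.atoms else []
    results = []
    for cdef in dictionary:
        if not _formula_compatible(component, cdef, missing_budget):
            continue
        m = match_component(component, cdef, bonds=bonds, missing_budget=missing_budget)
        if m is not None:
            results.append(m)

    def rank(m: ComponentMatch):
        n_other = sum(1 for k in m.missing_atoms.values() if k == "other")
        rmsd = m.rmsd_after_fit if not math.isnan(m.rmsd_after_fit) else math.inf
        return (n_other, len(m.missing_atoms), rmsd, m.comp_id)

    return sorted(results, key=rank)


def rename_atoms(component: ObservedComponent, match: ComponentMatch) -> ObservedComponent:
    """Rename observed atoms to the dictionary nomenclature of the match.

    Coordinates are untouched; unmapped observed atoms keep their original
    names (they are listed in ``match.extra_atoms``)."""
    for idx in match.atom_map:
        if idx >= len(component.atoms):
            raise MatcherError(f"atom map references absent atom index {idx}")
    new_atoms = [
        replace(atom, atom_name=match.atom_map.get(idx, atom.atom_name), comp_id=match.comp_id)
        for idx, atom in enumerate(component.atoms)
    ]
    return replace(component, comp_id=match.comp_id, atoms=new_atoms)


def signed_volume(center: np.ndarray, neighbors: np.ndarray) -> float:
    """Signed volume of the parallelepiped spanned by three substituent
    directions about a center — the handedness probe for tetrahedral
    stereocenters."""
    v = neighbors - center
    return float(np.linalg.det(v[:3])) / 6.0


_TYPICAL_VALENCE = {
    "C": 4, "N": 3, "O": 2, "S": 2, "P": 5, "B": 3, "F": 1,
    "CL": 1, "BR": 1, "I": 1, "SE": 2, "SI": 4,
}


def _assign_bond_orders(
    atoms: list[AtomSite], bonds: list[tuple[int, int]]
) -> list[str]:
    """Greedy valence-satisfaction heuristic for draft definitions.

    Every bond starts single; bonds between two under-valent atoms are
    upgraded to double, shortest first.  Planar six-membered rings of C/N
    are marked aromatic.  Draft quality by construction — curators adjust."""
    orders = ["SING"] * len(bonds)
    coords = np.array([a.xyz for a in atoms])
    degree = [0] * len(atoms)
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1

    g = nx.Graph(bonds)
    aromatic_bonds: set[frozenset[int]] = set()
    for ring in nx.cycle_basis(g):
        if len(ring) != 6:
            continue
        if any(atoms[i].element not in ("C", "N") for i in ring):
            continue
        pts = coords[ring]
        centered = pts - pts.mean(axis=0)
        # planarity: smallest singular value ~ out-of-plane extent
        if np.linalg.svd(centered, compute_uv=False)[-1] < 0.15:
            for k in range(6):
                aromatic_bonds.add(frozenset((ring[k], ring[(k + 1) % 6])))
    for bi, (i, j) in enumerate(bonds):
        if frozenset((i, j)) in aromatic_bonds:
            orders[bi] = "AROM"

    valence = [float(degree[i]) for i in range(len(atoms))]
    for i in range(len(atoms)):
        # an aromatic atom gets half-credit for each ring bond
        extra = sum(
            0.5 for bi, (a, b) in enumerate(bonds) if orders[bi] == "AROM" and i in (a, b)
        )
        valence[i] += extra

    lengths = [np.linalg.norm(coords[i] - coords[j]) for i, j in bonds]
    for bi in sorted(range(len(bonds)), key=lambda k: lengths[k]):
        if orders[bi] != "SING":
            continue
        i, j = bonds[bi]
        vi = _TYPICAL_VALENCE.get(atoms[i].element.upper())
        vj = _TYPICAL_VALENCE.get(atoms[j].element.upper())
        if vi is None or vj is None:
            continue
        # only bonds clearly shorter than the single-bond length are upgraded;
        # under-valence alone is expected when hydrogens are unobserved
        single = covalent_radius(atoms[i].element) + covalent_radius(atoms[j].element)
        if lengths[bi] <= single - 0.1 and valence[i] < vi and valence[j] < vj:
            orders[bi] = "DOUB"
            valence[i] += 1
            valence[j] += 1
    return orders


#: stereocenters flatter than this signed volume are left unassigned
STEREO_VOLUME_THRESHOLD = 0.1


def build_new_definition(
    component: ObservedComponent,
    proposed_id: str,
    dictionary: Sequence[ChemCompDef] = (),
) -> ChemCompDef:
    """Draft a new dictionary definition from an observed component.

    Connectivity comes from bond perception, bond orders from the valence
    heuristic, and tetrahedral stereocenters from the signed volume of the
    substituents (|V| > 0.1 A^3 to call handedness).  Model coordinates are
    the observed ones; ideal coordinates are left absent rather than faked.
    """
    proposed_id = proposed_id.upper()
    if any(d.comp_id == proposed_id for d in dictionary):
        raise MatcherError(f"proposed component id {proposed_id!r} already in dictionary")
    bonds = perceive_bonds(component)
    orders = _assign_bond_orders(component.atoms, bonds)
    coords = np.array([a.xyz for a in component.atoms])

    adjacency: dict[int, list[int]] = {i: [] for i in range(len(component.atoms))}
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)

    names: list[str] = []
    counters: dict[str, int] = {}
    for a in component.atoms:
        if a.atom_name and a.atom_name not in names:
            names.append(a.atom_name)
        else:
            counters[a.element] = counters.get(a.element, 0) + 1
            names.append(f"{a.element}{counters[a.element]}")

    atom_defs = []
    for idx, a in enumerate(component.atoms):
        stereo = "N"
        nb = adjacency[idx]
        if a.element == "C" and len(nb) >= 3:
            vol = signed_volume(coords[idx], coords[sorted(nb, key=lambda k: names[k])[:3]])
            if abs(vol) > STEREO_VOLUME_THRESHOLD:
                stereo = "R" if vol > 0 else "S"
        atom_defs.append(
            AtomDef(
                atom_id=names[idx],
                element=a.element,
                stereo_config=stereo,
                model_xyz=tuple(a.xyz),
                ideal_xyz=None,
            )
        )

    bond_defs = [
        BondDef(atom_id_1=names[i], atom_id_2=names[j], order=orders[bi],
                aromatic=orders[bi] == "AROM")
        for bi, (i, j) in enumerate(bonds)
    ]
    weight = sum(gemmi.Element(a.element).weight for a in component.atoms)
    return ChemCompDef(
        comp_id=proposed_id,
        name=f"draft definition for {proposed_id}",
        formula=formula_from_atoms(atom_defs),
        formula_weight=round(weight, 3),
        atoms=atom_defs,
        bonds=bond_defs,
        release_status="draft",
    )
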