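"""Ligand validation: geometry against dictionary ideal coordinates, and
the local ligand density fit (LLDF).

Geometry is compared to the values implied by the dictionary's idealized
coordinates — per-bond and per-angle deviations, plus chirality flips
detected by signed volume.  The LLDF is a Z-score of the ligand's
real-space R-value (RSR) against the mean and standard deviation of the
RSR of the neighboring polymeric standard residues within 5 A of any
ligand atom (crystallographic symmetry included); values above 2 flag the
ligand as fitting its density poorly.  RSR values themselves are inputs,
supplied as a per-residue table.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .matcher import ComponentMatch, signed_volume
from .sites import SiteParams, _contacts_for_group
from .structure import (
    ObservedComponent,
    ResidueKey,
    StructureModel,
    STANDARD_AMINO_ACIDS,
    STANDARD_NUCLEOTIDES,
)
from .ccd import ChemCompDef

__all__ = [
    "GeometryReport",
    "RsrTable",
    "LldfResult",
    "ValidationError",
    "geometry_check",
    "lldf",
    "validation_report",
    "BOND_SIGMA",
    "ANGLE_SIGMA",
    "LLDF_FLAG_THRESHOLD",
    "LLDF_CUTOFF",
]

BOND_SIGMA = 0.02  # A, fixed width for the bond rmsZ proxy
ANGLE_SIGMA = 2.0  # degrees, fixed width for the angle rmsZ proxy
LLDF_FLAG_THRESHOLD = 2.0
LLDF_CUTOFF = 5.0  # A


class ValidationError(ValueError):
    pass


@dataclass
class GeometryReport:
    #: (atom1, atom2) -> observed - ideal bond length, A
    bond_deviations: dict[tuple[str, str], float] = field(default_factory=dict)
    #: (atom1, center, atom2) -> observed - ideal angle, degrees
    angle_deviations: dict[tuple[str, str, str], float] = field(default_factory=dict)
    chirality_flips: list[str] = field(default_factory=list)
    ideal_available: bool = True
    notice: Optional[str] = None

    @property
    def bond_rmsz(self) -> float:
        if not self.bond_deviations:
            return math.nan
        dev = np.array(list(self.bond_deviations.values())) / BOND_SIGMA
        return float(np.sqrt(np.mean(dev**2)))

    @property
    def angle_rmsz(self) -> float:
        if not self.angle_deviations:
            return math.nan
        dev = np.array(list(self.angle_deviations.values())) / ANGLE_SIGMA
        return float(np.sqrt(np.mean(dev**2)))


def _angles_from_bonds(bonds: Sequence[tuple[str, str]]) -> list[tuple[str, str, str]]:
    """All atom triples a-c-b where both a-c and b-c are bonds: the bonded
    angles implied by a connectivity table."""
    adj: dict[str, list[str]] = {}
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    angles = []
    for center, nbrs in adj.items():
        nbrs = sorted(nbrs)
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                angles.append((nbrs[i], center, nbrs[j]))
    return angles


def _angle(p1: np.ndarray, pc: np.ndarray, p2: np.ndarray) -> float:
    v1, v2 = p1 - pc, p2 - pc
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def geometry_check(
    component: ObservedComponent,
    match: ComponentMatch,
    cdef: ChemCompDef,
) -> GeometryReport:
    """Deviations of the observed geometry from the dictionary's ideal
    geometry, over every dictionary bond and bonded angle whose atoms are
    all observed; chirality compared by the sign of the substituent
    volume about each assigned stereocenter."""
    name_to_idx = {atom_id: idx for idx, atom_id in match.atom_map.items()}
    obs_xyz = {aid: np.asarray(component.atoms[idx].xyz) for aid, idx in name_to_idx.items()}

    ideal = {a.atom_id: a.ideal_xyz for a in cdef.atoms if a.ideal_xyz is not None}
    report = GeometryReport(ideal_available=bool(ideal))
    if not ideal:
        report.notice = f"{cdef.comp_id}: no ideal coordinates; geometry limited to chirality"

    heavy_bonds = [
        (b.atom_id_1, b.atom_id_2)
        for b in cdef.bonds
        if not cdef.atom(b.atom_id_1).is_hydrogen and not cdef.atom(b.atom_id_2).is_hydrogen
    ]
    if ideal:
        for a1, a2 in heavy_bonds:
            if a1 in obs_xyz and a2 in obs_xyz and a1 in ideal and a2 in ideal:
                d_obs = float(np.linalg.norm(obs_xyz[a1] - obs_xyz[a2]))
                d_ref = float(np.linalg.norm(np.subtract(ideal[a1], ideal[a2])))
                report.bond_deviations[(a1, a2)] = d_obs - d_ref
        for a1, c, a2 in _angles_from_bonds(heavy_bonds):
            if all(x in obs_xyz and x in ideal for x in (a1, c, a2)):
                ang_obs = _angle(obs_xyz[a1], obs_xyz[c], obs_xyz[a2])
                ang_ref = _angle(*(np.asarray(ideal[x]) for x in (a1, c, a2)))
                report.angle_deviations[(a1, c, a2)] = ang_obs - ang_ref

    adj: dict[str, list[str]] = {}
    for a1, a2 in heavy_bonds:
        adj.setdefault(a1, []).append(a2)
        adj.setdefault(a2, []).append(a1)
    ref_coords = ideal if ideal else {
        a.atom_id: a.model_xyz for a in cdef.atoms if a.model_xyz is not None
    }
    for atom in cdef.atoms:
        if atom.stereo_config not in ("R", "S"):
            continue
        nbrs = sorted(adj.get(atom.atom_id, []))
        if len(nbrs) < 3:
            continue
        if atom.atom_id not in obs_xyz or any(n not in obs_xyz for n in nbrs[:3]):
            continue
        if atom.atom_id not in ref_coords or any(n not in ref_coords for n in nbrs[:3]):
            continue
        v_obs = signed_volume(obs_xyz[atom.atom_id], np.array([obs_xyz[n] for n in nbrs[:3]]))
        v_ref = signed_volume(
            np.asarray(ref_coords[atom.atom_id]),
            np.array([ref_coords[n] for n in nbrs[:3]]),
        )
        if v_obs * v_ref < 0:
            report.chirality_flips.append(atom.atom_id)
    return report


class RsrTable:
    """Per-residue real-space R-values, keyed by author address.

    The input is tab-separated text with columns chain, seq, ins, comp_id,
    rsr (header optional); '.' or '-' denote an empty insertion code."""

    COLUMNS = ("chain", "seq", "ins", "comp_id", "rsr")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame["ins"] = frame["ins"].fillna("").replace({".": "", "-": "", "?": ""})
        frame["seq"] = frame["seq"].astype(int)
        frame["rsr"] = frame["rsr"].astype(float)
        if (frame["rsr"] < 0).any():
            raise ValidationError("RSR values must be non-negative")
        self.frame = frame
        self._index = {
            (r.comp_id, r.chain, int(r.seq), r.ins): float(r.rsr)
            for r in frame.itertuples()
        }

    @classmethod
    def from_tsv(cls, text: str) -> "RsrTable":
        buf = io.StringIO(text)
        first = buf.readline()
        buf.seek(0)
        has_header = first.lower().split("\t")[0].strip() in ("chain", "#chain")
        frame = pd.read_csv(
            buf, sep="\t", comment=None,
            header=0 if has_header else None,
            names=None if has_header else list(cls.COLUMNS),
            dtype={"chain": str, "ins": str, "comp_id": str},
            keep_default_na=True, na_values=[""],
        )
        frame.columns = [c.lstrip("#") for c in frame.columns]
        return cls(frame)

    def to_tsv(self) -> str:
        out = self.frame.copy()
        out["ins"] = out["ins"].replace({"": "."})
        return out.to_csv(sep="\t", index=False)

    def get(self, key: ResidueKey) -> Optional[float]:
        return self._index.get(key)

    def __len__(self) -> int:
        return len(self._index)


@dataclass
class LldfResult:
    ligand: ResidueKey
    ligand_rsr: float
    neighbors: list[ResidueKey]
    mean_rsr: float
    sd_rsr: float
    lldf: float

    @property
    def n_neighbors(self) -> int:
        return len(self.neighbors)

    @property
    def flagged(self) -> bool:
        return self.lldf > LLDF_FLAG_THRESHOLD


def _standard_polymer_residue(comp: ObservedComponent) -> bool:
    return comp.is_polymer_residue and (
        comp.comp_id in STANDARD_AMINO_ACIDS or comp.comp_id in STANDARD_NUCLEOTIDES
    )


def lldf(
    model: StructureModel,
    rsr: RsrTable,
    ligand: Union[ObservedComponent, Sequence[ObservedComponent]],
    cutoff: float = LLDF_CUTOFF,
    use_symmetry: Optional[bool] = None,
) -> LldfResult:
    """LLDF of one ligand (or one multi-component group sharing an RSR row).

    Neighbors are the polymeric standard residues (amino acids and
    nucleotides) with any atom — or symmetry image — within ``cutoff`` of
    any ligand atom; the same contact engine as binding-site delineation is
    used.  The Z-score uses the sample (n-1) standard deviation; fewer than
    two neighbor RSR values leave the score undefined, which is an error.
    """
    group = [ligand] if isinstance(ligand, ObservedComponent) else list(ligand)
    lig_key = group[0].residue_key
    lig_rsr = rsr.get(lig_key)
    if lig_rsr is None:
        raise ValidationError(f"ligand {lig_key} missing from the RSR table")

    params = SiteParams(cutoff=cutoff, include_waters_as_neighbors=False,
                        use_symmetry=use_symmetry)
    contacts = _contacts_for_group(model, group, params)

    values: list[float] = []
    neighbors: list[ResidueKey] = []
    seen: set[ResidueKey] = set()
    for contact in contacts:
        key = contact.residue
        if key in seen:
            continue
        try:
            comp = model.component(key)
        except KeyError:
            continue
        if not _standard_polymer_residue(comp):
            continue
        v = rsr.get(key)
        if v is None:
            continue
        seen.add(key)
        neighbors.append(key)
        values.append(v)

    if len(values) < 2:
        raise ValidationError(
            f"ligand {lig_key}: only {len(values)} neighbor RSR values within "
            f"{cutoff} A; standard deviation not estimable"
        )
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise ValidationError(f"ligand {lig_key}: neighbor RSR standard deviation is zero")
    return LldfResult(
        ligand=lig_key,
        ligand_rsr=lig_rsr,
        neighbors=neighbors,
        mean_rsr=mean,
        sd_rsr=sd,
        lldf=(lig_rsr - mean) / sd,
    )


def validation_report(
    geometry: dict[ResidueKey, GeometryReport],
    density: Sequence[LldfResult],
) -> str:
    """Structured validation summary: JSON payload followed by a
    human-readable list of flagged ligands."""
    payload = {
        "geometry": {
            "/".join(map(str, key)): {
                "n_bonds": len(rep.bond_deviations),
                "n_angles": len(rep.angle_deviations),
                "bond_rmsz": None if math.isnan(rep.bond_rmsz) else round(rep.bond_rmsz, 3),
                "angle_rmsz": None if math.isnan(rep.angle_rmsz) else round(rep.angle_rmsz, 3),
                "chirality_flips": rep.chirality_flips,
            }
            for key, rep in geometry.items()
        },
        "lldf": [
            {
                "ligand": "/".join(map(str, r.ligand)),
                "ligand_rsr": round(r.ligand_rsr, 4),
                "n_neighbors": r.n_neighbors,
                "mean_rsr": round(r.mean_rsr, 4),
                "sd_rsr": round(r.sd_rsr, 4),
                "lldf": round(r.lldf, 2),
                "flagged": r.flagged,
            }
            for r in density
        ],
    }
    lines = [json.dumps(payload, indent=2), "", "Flagged ligands (LLDF > 2):"]
    flagged = [r for r in density if r.flagged]
    if flagged:
        for r in flagged:
            lines.append(f"  {'/'.join(map(str, r.ligand))}  LLDF={r.lldf:.2f}")
    else:
        lines.append("  none")
    return "\n".join(lines) + "\n"
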