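# ligannot

A toolkit for annotating small molecules in macromolecular crystal
structures, re-creating the core of an archive-curation pipeline as a
reusable Python library with a thin command-line interface.

Structural biologists depositing or curating protein–ligand structures need
the same few operations over and over: identify every observed small
molecule against a chemical component dictionary (CCD), standardize its
atom nomenclature, delineate its binding site with crystallographic
symmetry taken into account, record covalent linkages and metal
coordination, classify peptide-like inhibitors and antibiotics, and check
how well each ligand fits its experimental evidence. `ligannot` implements
each of those steps over the standard file formats (PDB, PDBx/mmCIF, the
CCD CIF dialect, PRD/FAM reference files, per-residue RSR tables).

## What it computes

- **Dictionary handling** (`ligannot.ccd`) — parse, validate and write CCD
  definitions: atoms with *leaving-atom* flags (atoms eliminated on
  covalent attachment, e.g. the anomeric O1 of a pyranose forming a
  glycosidic bond), bonds with orders, opaque SMILES/InChI descriptors.
- **Component identification** (`ligannot.matcher`) — bonds are perceived
  from coordinates with the covalent-radius criterion
  *d*(i,j) ≤ r_cov(i) + r_cov(j) + 0.45 Å, and the observed element-labeled
  graph is matched into dictionary graphs, tolerating absent hydrogens,
  eliminated leaving atoms and bounded disorder. Novel molecules get a
  draft definition (heuristic bond orders, signed-volume stereocenters).
- **Binding sites** (`ligannot.sites`) — a site is every residue with any
  atom, or crystallographic symmetry image of an atom, within **3.7 Å** of
  any ligand atom; multi-component molecules (oligosaccharides, peptide-like
  groups) are treated as one ligand. Sites get identifiers AC1…ZZ9 and are
  written as `_struct_site` / `_struct_site_gen`.
- **Linkages and metals** (`ligannot.linkages`) — inter-component atom
  pairs in covalent range become `_struct_conn` records (covale / disulf /
  metalc); each metal center gets all k(k−1)/2 pairwise ligator–metal–ligator
  angles, written as REMARK 620 and `_pdbx_struct_conn_angle`.
- **Peptide-like classification** (`ligannot.bird`) — a molecule with two
  or more consecutive peptide bonds is represented as a polymer; with fewer,
  as a non-polymer with its subcomponent sequence recorded N→C; sugar or
  fatty-acid attachments on the peptide core force the group representation.
  PRD/FAM reference files round-trip.
- **Ligand validation** (`ligannot.validation`) — geometry deviations
  against dictionary ideal coordinates, and the local ligand density fit

  LLDF = (RSR_ligand − mean RSR_neighbors) / sd RSR_neighbors,

  where neighbors are the polymeric standard residues within **5 Å** of any
  ligand atom (symmetry included) and sd is the sample (n−1) standard
  deviation; LLDF > 2 flags the ligand.
- **Synthetic fixtures** (`ligannot.fixtures`) — deterministic generators
  for every input above (chair-conformation sugar, amino acid, aromatic
  ring, crystal scenes in P1/P21/P2₁2₁2₁, sugar macrocycles, metal centers,
  RSR tables), each with ground truth computed by independent brute-force
  code.

## Worked example

Generate a synthetic orthorhombic scene and run the full pipeline:

```sh
$ ligannot fixture --scene random --seed 11 --space-group "P 21 21 21" --out demo
$ ligannot annotate demo/fixture.cif --out demo
1 ligands (1 identified), 1 sites, 0 linkages, 0 metal centers
$ ligannot sites demo/fixture.cif --out demo && head -2 demo/site_contacts.tsv
site_id comp_id chain seq sym   dist
AC1     ALA     A     3   2_564 2.133
```

The one ligand was identified against the dictionary; its binding site AC1
contains residue ALA A 3 — but only through symmetry operator 2 with
lattice translation code 564, i.e. a neighboring copy of the chain in the
crystal, which a non-symmetry-aware contact search would have missed.

A sugar macrocycle (seven pyranoses joined by glycosidic bonds, each having
lost its leaving O1):

```sh
$ ligannot fixture --scene cyclodextrin --out cd
$ ligannot links cd/fixture.cif --out cd
7 linkages, 0 metal centers
```

Library-level density-fit validation:

```python
from ligannot import fixtures as fx
from ligannot.validation import lldf

model, _ = fx.placed_contact_scene(close=(3.0, 3.2, 3.4), far=())
table, _ = fx.make_rsr_fixture(model, ligand_offset=0.2, noise_sigma=0.02, seed=1)
r = lldf(model, table, model.ligands()[0])
print(f"RSR={r.ligand_rsr:.3f} neighbors={r.n_neighbors} "
      f"mean={r.mean_rsr:.3f} sd={r.sd_rsr:.3f} LLDF={r.lldf:.2f} flagged={r.flagged}")
```

prints

```
RSR=0.320 neighbors=3 mean=0.144 sd=0.009 LLDF=19.70 flagged=True
```

— the ligand's real-space R-value sits far above its environment, so it is
flagged as fitting the density poorly.

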