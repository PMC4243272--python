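# Methods

This note records the scientific choices behind `ligannot`: the procedures
implemented, the parameters that matter and why their defaults are what
they are, what the synthetic fixtures do and do not emulate, and the
numerical details a maintainer would otherwise have to reverse-engineer.

## Coordinate model and symmetry

All public coordinates are orthogonal ångströms; fractional coordinates
exist only inside the symmetry arithmetic. The orthogonalization matrix
follows the standard crystallographic convention (a along x, b in the xy
plane); `fractionalize` and `orthogonalize` are exact inverses to 1e-8 Å
and the matrix is cross-checked against an independent implementation in
the tests. Space-group operators are taken from gemmi's symmetry tables by
Hermann–Mauguin symbol; an unrecognized symbol is a hard error, and a model
without cell information can be parsed and annotated but refuses any
symmetry-aware operation rather than silently falling back to a
non-symmetric search.

Symmetry expansion returns, for a set of query atoms and a radius, every
operator-plus-lattice-shift image of every model atom within the radius,
labeled `op_index` + 555-style translation digits. Candidate lattice shifts
are centered on the rounded fractional offset between each image and each
query atom and extended ±1 cell in every direction; this is exhaustive
whenever the radius is smaller than the cell edges, and the test suite
asserts equality with a plain quintuple-loop enumeration (all operators ×
all shifts in (−2…2)³). The wider oracle range matters: a symmetry operator
can move coordinates outside the unit box, so shift digits beyond ±1 occur
even for atoms inside the cell. The identity-with-zero-shift copy of the
query atoms themselves is excluded; identity images of *other* atoms are
direct contacts and are kept, as are symmetry mates of the query molecule
(crystal-packing neighbors are legitimate site members). Only
crystallographic symmetry is considered; non-crystallographic symmetry is
out of scope.

Author numbering (chain, residue number, insertion code) is the public
addressing scheme throughout. Multi-model input uses model 1 unless asked
otherwise. For distance queries every alternate location is considered and
residue-level results keep the minimum over altlocs.

## Bond perception and component matching

Bonds are perceived from coordinates with the covalent-radius criterion
d ≤ r(i) + r(j) + tol, radii from gemmi's element tables, tol = 0.45 Å.
The tolerance admits stretched covalent bonds (~15 % beyond nominal) while
staying well below heavy-atom hydrogen-bond distances (≥ 2.4 Å); it is a
parameter on every perception call.

Matching treats the observed component as an element-labeled graph to be
embedded into the dictionary component's heavy-atom graph (a monomorphism:
every perceived bond must map onto a dictionary bond, but a missed
perceived bond does not disqualify). Hydrogens are never required —
X-ray depositions routinely omit them. Dictionary atoms may be absent from
the observation in two ways: leaving atoms (free of penalty — that is the
point of the leaving-atom annotation) and up to 20 % of heavy atoms as
unmodeled disorder (configurable budget). Bond orders are not compared;
they are unobservable from X-ray coordinates. Among all embeddings the
match with (fewest missing non-leaving atoms, lowest RMSD after Kabsch
superposition onto the dictionary model coordinates, lexicographically
smallest map) wins, which makes matching deterministic and invariant under
atom-order permutation and rigid motion. Candidate dictionary entries are
pre-filtered by heavy-atom element multiset before any graph search.

Draft definitions for novel molecules are declared draft quality
(`pdbx_release_status = draft`): bond orders come from a greedy heuristic
that marks planar six-membered C/N rings aromatic (out-of-plane extent
< 0.15 Å) and upgrades a bond to double only when both atoms are
under-valent *and* the bond is at least 0.1 Å shorter than the sum of
single-bond covalent radii — under-valence alone is expected when
hydrogens are unobserved, so length is the deciding evidence. Tetrahedral
carbon stereocenters are assigned from the signed volume of the first
three substituents in name order; |V| < 0.1 Å³ is treated as flat and left
unassigned. Ideal coordinates are never fabricated: drafts carry observed
coordinates as model coordinates and leave the ideal set absent.

## Binding sites

A site is delineated per non-polymeric, non-water ligand — or per declared
multi-component group — as every residue with any atom or symmetry image
within the cutoff (default 3.7 Å) of any ligand atom. Contacts are
deduplicated per (residue, symmetry label), keeping the minimum distance:
two distinct symmetry copies of the same residue are physically distinct
neighbors and appear as separate rows, matching how the symmetry attribute
qualifies each `_struct_site_gen` row. Residues of the ligand's own group
are never its contacts; waters count as neighbors by default (toggleable)
but never as ligands. Site identifiers follow the two-letters-plus-digit
scheme starting at AC1 with the digit cycling fastest (AC1…AC9, AD1, …);
the enumeration order is pinned by tests since only its start and alphabet
are externally fixed. The serialized `_struct_site_gen` rows carry the
contact distance in the details item so the category pair re-parses to the
same site objects.

## Linkages and metal coordination

Inter-component atom pairs within covalent range (same criterion as bond
perception, symmetry-aware) become linkages, except standard polymer
backbone bonds — peptide C–N and nucleic O3′–P between sequence-adjacent
residues of the same chain — which are implied by the polymer description.
Adjacency is checked on author numbering so genuine nonstandard
cross-links between non-neighboring residues survive. Classification:
Cys S–S pairs are disulfides; metal–donor pairs within the coordination
cutoff are `metalc`; everything else is `covale`.

Metal coordination uses an element-pair cutoff table (Zn–N/O 2.6 Å,
Zn–S 2.8 Å, Mg–O/N 2.6 Å, Ca–O/N 2.9 Å, Na/K–O/N 3.2 Å, default 3.0 Å),
values from common coordination-chemistry practice and configurable per
call. Ligators are N, O, S and halide atoms; alternate conformers
contribute separate ligators and the angle list covers every ligator pair,
including cross-conformer pairs, so a two-conformer carboxylate yields the
small O–M–O angles characteristic of bidentate binding. All k(k−1)/2
angles are computed about the metal and written identically (to 0.1°) as a
fixed-column REMARK 620 block and as `_pdbx_struct_conn_angle` rows; both
writers have re-parsers used for round-trip tests.

## Peptide-like representation rules

A peptide bond between subcomponents is an inter-subcomponent C–N bond in
which the carbon carries a double-bonded oxygen within its own
subcomponent and the nitrogen is bonded to at least one carbon of its own
subcomponent; the bond is directed carbonyl-C → amide-N, so following the
arrows runs N-terminus to C-terminus. Ester junctions fail the nitrogen
criterion. D-amino acids and N-methylated residues are treated identically
— the criterion is purely topological.

The classifier applies, in order: sugar or fatty-acid attachments on the
peptide core → GROUP; at least two consecutive peptide bonds → POLYMER;
otherwise NONPOLYMER_SUBCOMPONENTS with the subcomponent sequence recorded
N→C. GROUP takes precedence because a glycopeptide core typically has well
over two consecutive peptide bonds yet must stay a group. "Consecutive" is
the longest simple path in the peptide-bond graph; branch points
contribute their longest branch, and cyclic cores are walked from the
canonical start (lowest component id, then key order). One deliberate
subtlety: an N-acyl amide linking a fatty acid to the terminal nitrogen
satisfies the structural peptide-bond criterion, but saccharide- and
lipid-type subcomponents never join the peptide core, so the acyl chain
remains an attachment and the molecule classifies GROUP. Lipid-likeness is
a heuristic — a non-peptide, non-saccharide subcomponent with ≥ 4 carbons
and no nitrogen — adequate for acyl chains; exotic attachments may need an
explicit component-type annotation.

PRD/FAM reference files are implemented minimally: identity, class and
function strings, subcomponent chains, inter-subcomponent links, family
membership; unknown categories are not modeled here (the CCD reader, by
contrast, preserves unknown categories verbatim for round-trips). Family
members are validated against the set of loaded PRD identifiers.

## Ligand validation

Geometry is checked against values computed from the dictionary's ideal
coordinates: per-bond length deviations, per-angle deviations over all
bonded triples, and chirality by comparing the sign of the substituent
signed volume between observed and reference coordinates for every
assigned stereocenter. rmsZ summaries use fixed widths of 0.02 Å (bonds)
and 2° (angles) — a proxy scale, not a library of observed distributions,
which keeps the report self-contained. A definition without ideal
coordinates limits the report to chirality and says so.

The LLDF is a Z-score: (ligand RSR − mean neighbor RSR) / sd neighbor RSR,
neighbors being the polymeric standard residues (20 amino acids plus
standard nucleotides; modified residues excluded) with any atom or
symmetry image within 5 Å of any ligand atom. Neighbor selection reuses
the binding-site contact engine, and a test pins that equivalence. The
sample (n−1) standard deviation is used; with fewer than two neighbor
values, or an exactly zero spread, the score is undefined and raised as an
error rather than fabricated. Ligands with LLDF > 2 (strictly greater) are
flagged. RSR values are inputs, read from a tab-separated per-residue
table; computing RSR from maps is out of scope. For a multi-component
ligand one RSR row stands for the whole molecule, keyed by its first
component.

## Synthetic fixtures and what passing tests show

The generators build chemically consistent geometry from internal
coordinates: a chair pyranose with equatorial hydroxyls and the anomeric
O1 flagged as leaving; an amino acid with carboxy-terminal OXT/HXT and
amino H2 leaving atoms; an aromatic six-ring; water. Bond perception on
these fixtures reproduces their bond tables exactly, hydrogens included.
Crystal scenes place rigid copies at seeded random positions in cells of
16–24 Å so that symmetry images genuinely enter a 3.7 Å shell; the sugar
macrocycle joins seven pyranoses by 1.42 Å glycosidic O4→C1 bonds, with
the ring tilt chosen by a deterministic scan as the first orientation
whose only inter-unit covalent-range contact is the glycosidic bond
itself. RSR tables draw neighbor values from N(base = 0.12, σ = 0.02) with
the ligand offset above base, so the designed score is offset/σ.

All randomness derives from one integer seed through per-fixture counters,
so adding a generator never shifts an existing one and every fixture is
bit-reproducible. Ground truth comes from independent brute-force code
(explicit operator × shift enumeration through gemmi's cell arithmetic;
exhaustive assignment search for matching), not from the modules under
test.

These fixtures emulate topology, stoichiometry and crystal geometry — not
experimental reality: no coordinate noise beyond small jitter, no
occupancy or B-factor structure, idealized covalent distances, RSR values
drawn from a clean normal rather than resolution-dependent distributions.
Passing tests therefore demonstrate correctness of the declared procedures
(contact sets, graph matching, classification rules, the Z-score
arithmetic), not robustness to pathological experimental data.

A note on the Monte-Carlo LLDF check: with n neighbors the sample standard
deviation underestimates σ on average, so the mean observed Z-score
exceeds the designed offset/σ by the inverse-chi bias factor (≈ 1.13 at
n = 8). The acceptance scene uses eight neighbors, putting the expected
mean near 3.4 for a designed 3.0 — within the stated ±0.6 band and a
property of Z-scores generally, not of this implementation.

## Problem sizes

The default verification runs use 54 randomized contact scenes (~100 atoms
each) across three space groups, 40 matcher recovery cases over the four
fixture components, a 31-case classification truth table, and 200
generated RSR tables for the Monte-Carlo mean; the whole suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

- Matching is exact graph embedding; it will not recognize a component
  whose perceived connectivity differs from the dictionary (very distorted
  geometry), and the exponential worst case of subgraph search is only
  mitigated by the element pre-filter and the small size of typical
  ligands.
- Bond-order and aromaticity assignment in drafts is heuristic by design;
  tautomers, charged states and non-tetrahedral stereochemistry are not
  inferred.
- Coordination geometry is reported, not classified (no
  tetrahedral/octahedral labels, no valence-sum checks).
- NCS, biological assemblies, anisotropic displacement and electron-density
  maps are out of scope.
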