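# Methods

## The model

The unit of analysis is the **interaction motif**: two segments of four
consecutive residues, one on each binding partner, whose Cα centres of
mass (unweighted means of the four Cα positions) lie within a cutoff.
"Consecutive" is geometric, not numeric: two residues are consecutive iff
they share a chain and their Cα–Cα distance is below 4.5 Å, so
crystallographic chain breaks and missing backbone atoms terminate
windows regardless of author numbering. Windows overlap freely
(stride 1).

A motif's shape is the vector of its 28 internal Cα–Cα distances in a
fixed order (segment A residues 1–4 then segment B residues 1–4, all
pairs i<j). This representation is invariant to rotation, translation
*and reflection*; matching therefore has two stages:

1. **dRMSD prefilter** — root-mean-square difference of the two distance
   vectors, threshold 1 Å. This vectorises over the whole database as a
   single array operation. Swapping which database segment aligns with
   which target segment permutes the 28-vector by a fixed permutation, so
   the partner-swapped orientation is screened at the same cost.
2. **Proper superposition RMSD** — Kabsch superposition (SVD with the
   determinant-sign correction; reflections forbidden) of the 8 Cα atoms,
   threshold 1 Å. This restores chirality: a mirror-image motif passes
   stage 1 with dRMSD = 0 and is rejected here.

The prefilter is part of the match definition, not merely an
optimisation: dRMSD ≤ 2·RMSD is the only bound that holds in general
(each pair-distance error is at most the sum of the two endpoint errors;
summing over the 7 pairs per atom gives the factor 2, and a property
test asserts it), so borderline pairs with superposition RMSD just under
1 Å can carry dRMSD above 1 Å and are excluded — by both thresholds, in
either order. The fast path (vectorised prefilter, Kabsch on survivors)
is regression-tested against a slow path that superposes every pair and
applies both thresholds per pair.

Within-segment N→C order is never reversed: backbone directionality
makes a reversed graft chemically meaningless. Partner swap is on by
default and can be disabled (`--no-swap`) for strict directional
matching.

## Database construction

Per corpus complex: skip if either partner has fewer than 40 residues or
the buried interface area is below 1,000 Å²; extract motifs at an 11 Å
segment-COM cutoff (1 Å wider than the 10 Å used on the target side, so
large side-chain contacts at the horizon are not lost); pool. Pooled
motifs must contain at least 3 nonpolar or aromatic residues out of 8
(the set ALA VAL LEU ILE MET PRO CYS PHE TRP TYR; CYS counted nonpolar,
HIS excluded) and are then de-duplicated by a greedy pass in corpus
order: a motif is kept iff its dRMSD to every previously kept motif
exceeds 1 Å. The greedy order (file order, then window enumeration
order) is fixed, so builds are bit-reproducible; every stage count is
recorded in the database's `build_params`.

Buried area is (SASA(A) + SASA(B) − SASA(AB))/2; the halving convention
is a config switch (`halved=False`) since either convention is found in
the literature. SASA is Shrake–Rupley with a deterministic golden-spiral
point set (960 points/atom by default; doubling the count changes fixture
totals by <0.5 %), probe 1.4 Å, and vdW radii C 1.70 / N 1.55 / O 1.52 /
S 1.80 / P 1.80 Å. Exactly coincident equal-radius atoms are counted
once, which makes the degenerate fully-overlapping case well defined
under the strict `<` burial comparison. All comparisons against cutoffs
(interface membership, COM cutoffs, clash distance) are strict `<`; the
match thresholds (dRMSD, RMSD) are inclusive `≤`.

The database file is JSON (optionally gzipped) with a magic header and a
format version; loading verifies both and fails loudly on truncation.
Distance vectors are recomputed from the stored Cα coordinates at load,
so the recompute-invariant (|stored − recomputed| < 1e-9) holds by
construction.

## Redesign

Each match aligns a database motif onto eight target positions. Per
position, the residue identities contributed by all matches are tallied;
candidates are ranked by count, then by mean RMSD of their contributing
matches, then alphabetically. Positions are processed in order of
descending total coverage (ties by position), and at each position
candidates are tried in rank order:

- a top candidate equal to the native residue confirms the native side
  chain and the position is left untouched (CONFIRMED_NATIVE);
- otherwise the side chain from the candidate's best-RMSD match is
  grafted by superposing the source residue's N/CA/C frame onto the
  target's (3-atom Kabsch) and carrying the side-chain heavy atoms along;
  the graft keeps the target backbone (N, CA, C, O) and adopts the source
  name and side chain. Per-residue frames rather than the whole-motif
  transform keep ≤1 Å backbone mismatch from leveraging into side-chain
  displacement; the whole-motif transform is available behind a flag.
- the graft is accepted iff no side-chain heavy atom comes within 2.5 Å
  of any heavy atom of another residue, excluding the peptide
  neighbours' backbone N/C/O. Accepted grafts join the working structure
  and constrain later positions (sequential clash checking).

2.5 Å is a conventional hard-core heavy-atom distance; it is a flag, as
the underlying notion ("no significant steric overlap") has no canonical
number. No rotamer optimisation is performed — the premise of the method
is that motif side chains come from well-packed native interfaces and
are transplanted as-is. Backbone coordinates are bit-identical before
and after redesign. Frequency counts matches, not unique source
complexes, so a homolog-rich database can bias tallies.

The redesigned PDB carries a REMARK that it is unminimized; the intended
workflow feeds it to an external molecular-mechanics minimizer. Energy
evaluation of any kind is out of scope here.

## Partner displacement and placement scanning

The displacement operation translates partner B along the unit vector
between the two partners' interface-atom centres of mass (heavy atoms
within 10 Å of the other partner, unweighted). A displacement *series*
is defined along the line fixed by its reference pose — interface
membership changes as the partners separate, which would otherwise bend
the line — so the series helper computes the axis once and passes it
explicitly.

The placement scan enumerates the full cubic grid of translations of
partner B, (2·radius/step + 1)³ points including the origin, runs the
matcher at each, and ranks placements by match count (descending), mean
match RMSD (ascending, no-match poses last), then lexicographic
translation. Note that at the default 1 Å thresholds the raw match
*count* can peak a little off the true pose, because near-threshold
matches count the same as exact ones; plant-and-recover demonstrations
use strict thresholds (dRMSD 0.5 / RMSD 0.25 Å), where the recovered
pose dominates both count and mean RMSD.

Pose quality metrics follow the interface/ligand conventions:
IRMSD superposes the heavy atoms of the reference-interface residues
(10 Å heavy-atom interface) and reports their RMSD; LRMSD superposes
partner A (receptor) and reports partner B's RMSD without refitting.
Both are invariant to global rigid motion of the model.

## The synthetic fixture generator

All tests and the acceptance script run on generated data. The generator
builds ideal α-helices by internal-coordinate (NeRF) construction at
φ = −57.8°, ψ = −47°, ω = 180° with ideal backbone bonds/angles
(verified: consecutive Cα–Cα = 3.80 Å, dihedrals exact), grafts
single-conformer ideal side chains from chemical-component reference
templates via the local backbone frame, and assembles two-helix
complexes with controlled inter-axial distance, crossing angle,
parallel/antiparallel sense and helical phase. Sequences are drawn
deterministically from a hydrophobic-rich alphabet so motifs pass the
composition filter.

Each complex receives seeded Gaussian coordinate noise (σ = 0.15 Å per
coordinate). This emulates the coordinate heterogeneity of real
structures and is load-bearing: perfectly ideal helix pairs have
near-exact screw symmetry, so shifted window pairs are *true geometric
homologs carrying different sequences*, which defeats strict-threshold
self-recovery in a way real, irregular interfaces do not. The bundled
corpus is five helix pairs with distinct packing geometries
(inter-axial 8–9.5 Å, one parallel, one crossed at 35°, varied phase) so
that redundancy reduction keeps each complex's motifs as its own
representatives.

What the fixtures do *not* emulate: loops and sheets, rotamer diversity,
missing atoms/altlocs in the corpus (exercised by small hand-built PDB
fixtures instead), sequence–structure correlation, and homology between
corpus entries. Passing tests therefore demonstrate the correctness of
the machinery — extraction, filtering, matching geometry, grafting,
steric control — not the biological quality of redesigns on real
complexes, which additionally depends on the size and diversity of a
real motif database.

Problem sizes used by the test suite and acceptance script — a
5-complex corpus (12–14 residues per helix, ~300 pooled motifs, ~150
after reduction), 1,000 random motifs for reduction semantics, and a
10,000-motif synthetic database for throughput — were chosen as the
smallest sets on which every pipeline property is non-trivially
exercised; matching one fixture interface against the 10,000-motif
database takes well under a second.

## Known limitations

- Two-partner (two chain-group) complexes only; no assemblies, no
  mmCIF, no hydrogens, no altloc output.
- The dRMSD prefilter is exact all-pairs screening; no approximate
  nearest-neighbour index. Throughput is far inside the budget at
  10⁴–10⁵ motifs, which is the regime of curated interface corpora.
- Rotational placement search is not implemented (translational grid
  only).
- The redesign is greedy and order-dependent by design; the order
  (coverage-ranked) is deterministic and documented, but a different
  order could accept a different, equally clash-free set of
  substitutions.
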