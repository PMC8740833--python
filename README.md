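# motifmatch

Knowledge-based redesign of protein–protein interfaces from recurring
backbone interaction motifs.

Designing or refining a protein–protein binding interface usually means
deciding, for a desired relative arrangement of two proteins, which side
chains to place at the contact surface. `motifmatch` answers that question
with statistics from known complex structures instead of energy
calculations: it extracts **interaction motifs** — a pair of four
consecutive residues, one segment on each binding partner, whose Cα
centres of mass lie within a cutoff — from a corpus of two-partner complex
structures, stores them in a searchable database, finds the database
motifs that reproduce the backbone geometry of a user-supplied target
interface, and grafts the most frequently observed non-clashing side
chains onto the target. It is written for structural bioinformaticians and
protein designers who want a fast, interpretable first pass before
force-field refinement.

## Method

A motif's geometry is summarised by its 28 internal Cα–Cα distances
(all pairs of the 8 Cα atoms, segment A then segment B). Two motifs are
compared first by the root-mean-square deviation of those distances,

    dRMSD(v, w) = sqrt( (1/28) Σ_k (v_k − w_k)² ),

which is rotation-, translation- and reflection-invariant and vectorises
over the whole database, and then — for prefilter survivors — by the
minimal coordinate RMSD under *proper* rigid superposition (Kabsch, SVD
with determinant correction; reflections forbidden, which restores the
chirality sensitivity the distance stage lacks). A match requires both
dRMSD ≤ 1 Å and superposition RMSD ≤ 1 Å by default.

Database construction follows the corpus-curation rules: complexes with a
buried interface area below 1,000 Å² (Shrake–Rupley SASA) or a partner
below 40 residues are excluded; motifs are extracted at an 11 Å
segment-COM cutoff, must contain at least three nonpolar or aromatic
residues, and are greedily de-duplicated at 1 Å dRMSD.

Redesign tallies, per target interface position, the residue identities
contributed by all matches at the aligned segment slot; candidates are
tried in frequency order and accepted if the side chain — transplanted
via per-residue N/CA/C frame superposition — keeps every heavy atom at
least 2.5 Å from other residues. Backbone atoms never move. The output
PDB is intentionally unminimized; refine it with your molecular-mechanics
package of choice.

## Worked example

No downloads are needed: the package ships a deterministic synthetic
fixture generator (ideal α-helix pairs with full side chains and seeded
coordinate noise) that exercises every stage.

```sh
python examples/build_database.py
```

```
complexes included : 5
motifs extracted   : 301
after composition  : 301
after reduction    : 147
```

301 motifs are pooled from the five fixture complexes; redundancy
reduction keeps 147 geometrically distinct ones (the composition filter
removes nothing here because the fixture sequences are hydrophobic-rich).

```sh
python examples/match_and_redesign.py
```

```
RMSD threshold 1.00 Å: 104 matches, 3 accepted changes, 21 positions confirmed native
RMSD threshold 0.25 Å:  41 matches, 0 accepted changes, 22 positions confirmed native

Accepted substitutions at the default threshold:
  A7   MET -> LEU (seen in 26 matches)
  A10  SER -> VAL (seen in 11 matches)
  B1   VAL -> THR (seen in 4 matches)
```

At the default 1 Å threshold, motifs from the *other* complexes suggest a
few substitutions; at 0.25 Å only the target's own motifs survive and the
native interface sequence is recovered exactly — the self-recovery
property that validates the pipeline end to end.

```sh
python examples/displacement_series.py
```

```
displacement  LRMSD   matches
    0.0 Å     0.00 Å    110
    1.0 Å     1.00 Å     65
    2.0 Å     2.00 Å      0
    3.0 Å     3.00 Å      0
    4.0 Å     4.00 Å      0
```

Pulling the partners apart along the interface-COM axis destroys matches
within 1–2 Å: motifs encode tightly packed native contacts, so the input
arrangement must be placed to about 1 Å. `examples/placement_scan.py`
shows the converse — a 1 Å translational grid scan recovering a
deliberately mis-placed pose.

## Command line

The same pipeline is available as a single `motifmatch` binary:

```sh
motifmatch make-fixtures --out fixtures/ --seed 7
motifmatch build-db --corpus fixtures/ --manifest fixtures/manifest.tsv \
    --min-interface-area 0 --min-partner-residues 0 -o motifs.json.gz
motifmatch match fixtures/fix0.pdb --db motifs.json.gz \
    --partner-a A --partner-b B -o matches.json --write-motifs matches.pdb
motifmatch redesign fixtures/fix0.pdb --db motifs.json.gz \
    --partner-a A --partner-b B -o redesigned.pdb --report report
motifmatch metrics --ref native.pdb --model pose.pdb --partner-a A --partner-b B
```

`matches.pdb` contains each matched database motif transformed into the
target frame as a separate MODEL for inspection in a molecular viewer.
The database file is JSON (optionally gzip) with a `MOTIFMATCH-DB` magic
header and a format version; loading rejects truncated files and unknown
versions explicitly.

## Scope

Energy minimization of the redesigned complex (the output PDB carries a
remark that it is unminimized), docking, and rotational placement search
are out of scope; `docs/methods.md` documents the model, parameter
defaults, numerical conventions and limitations.
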