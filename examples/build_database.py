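"""Build a motif database from the bundled synthetic corpus.

Writes the five fixture complexes to disk, extracts all 4+4-residue
interaction motifs at the 11 Å segment-COM cutoff, applies the
nonpolar-composition filter and the 1 Å dRMSD redundancy reduction, and
saves the database. The printed stage counts show how many motifs each
filter removed.
"""

import tempfile
from pathlib import Path

from motifmatch import build_database, save_database
from motifmatch.fixtures import write_fixture_corpus

with tempfile.TemporaryDirectory() as td:
    corpus = Path(td) / "corpus"
    manifest = write_fixture_corpus(corpus, seed=7)
    # the synthetic helices are far smaller than real complexes, so the
    # corpus-inclusion thresholds (1,000 Å² interface, 40-residue partners)
    # are disabled here
    db = build_database(corpus, manifest, min_interface_area=0,
                        min_partner_residues=0)
    save_database(db, Path(td) / "motifs.json.gz")
    counts = db.build_params["counts"]
    print(f"complexes included : {counts['included']}")
    print(f"motifs extracted   : {counts['extracted']}")
    print(f"after composition  : {counts['after_composition_filter']}")
    print(f"after reduction    : {counts['after_reduction']}")
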