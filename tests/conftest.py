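import numpy as np
import pytest

from motifmatch import (FixtureSpec, make_complex_fixture, make_fixture_database,
                        default_fixture_specs)

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.391   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.760   1.200  1.00  0.00           C
ATOM      6  N   SER A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  SER A   2       3.970   2.852   0.000  1.00  0.00           C
ATOM      8  C   SER A   2       5.480   2.700   0.000  1.00  0.00           C
ATOM      9  O   SER A   2       6.030   1.600   0.000  1.00  0.00           O
ATOM     10  CB ASER A   2       3.500   3.700   1.200  0.60  0.00           C
ATOM     11  OG ASER A   2       3.900   5.050   1.100  0.60  0.00           O
ATOM     12  CB BSER A   2       3.450   3.750  -1.150  0.40  0.00           C
ATOM     13  OG BSER A   2       3.850   5.100  -1.050  0.40  0.00           O
ATOM     14  N   GLY A   3       6.150   3.850   0.000  1.00  0.00           N
ATOM     15  CA  GLY A   3       7.600   3.900   0.000  1.00  0.00           C
ATOM     16  C   GLY A   3       8.200   5.300   0.000  1.00  0.00           C
ATOM     17  O   GLY A   3       7.500   6.320   0.000  1.00  0.00           O
ATOM     18  N   LEU B   1       0.000   0.000   6.000  1.00  0.00           N
ATOM     19  CA  LEU B   1       1.458   0.000   6.000  1.00  0.00           C
ATOM     20  C   LEU B   1       2.009   1.420   6.000  1.00  0.00           C
ATOM     21  O   LEU B   1       1.251   2.391   6.000  1.00  0.00           O
ATOM     22  CB  LEU B   1       2.000  -0.760   7.200  1.00  0.00           C
ATOM     23  CG  LEU B   1       3.520  -0.900   7.250  1.00  0.00           C
ATOM     24  CD1 LEU B   1       3.950  -1.700   8.470  1.00  0.00           C
ATOM     25  CD2 LEU B   1       4.150   0.480   7.280  1.00  0.00           C
HETATM   26  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
HETATM   27  C1  LIG B 201      12.000  12.000  12.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def altloc_pdb(tmp_path_factory):
    """Hand-built 4-residue PDB: altloc pair on SER 2, a water and a ligand."""
    path = tmp_path_factory.mktemp("pdb") / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture(scope="session")
def fixture_corpus():
    """The bundled five-complex synthetic corpus with ground truth."""
    return [make_complex_fixture(s) for s in default_fixture_specs()]


@pytest.fixture(scope="session")
def fixture_db_and_corpus():
    """Default fixture motif database plus the generating complexes."""
    return make_fixture_database()


@pytest.fixture(scope="session")
def fixture_db(fixture_db_and_corpus):
    return fixture_db_and_corpus[0]


@pytest.fixture(scope="session")
def helix_pair():
    """One deterministic helix-pair complex (independent of the corpus)."""
    cs, truth = make_complex_fixture(FixtureSpec(seed=11, complex_id="hp", distance=8.5))
    return cs, truth


def random_ca_cloud(rng, n=8, scale=4.0) -> np.ndarray:
    return rng.normal(scale=scale, size=(n, 3))
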