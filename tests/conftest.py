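import numpy as np
import pytest

from esalign import FixtureSpec, make_chain, validate_chain

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
TER
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      6  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.000   0.000   9.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   9.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   9.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.332   1.536   9.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       3.988   2.839   9.000  1.00  0.00           C
ATOM      6  C   ALA A   2       5.504   2.693   9.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      4  C   ALA A   1       3.000   1.000   0.000  1.00  0.00           C
ATOM      5  N   ALA A   2       4.000   1.500   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       5.000   2.500   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       6.500   2.500   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture
def two_model_pdb_text():
    return TWO_MODEL_PDB


@pytest.fixture
def altloc_pdb_text():
    return ALTLOC_PDB


@pytest.fixture
def helix_chain():
    return validate_chain(make_chain(FixtureSpec(n_residues=50, family="helix", seed=1)))


@pytest.fixture
def strand_chain():
    return validate_chain(make_chain(FixtureSpec(n_residues=50, family="strand", seed=2)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
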