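import numpy as np
import pytest

import coronams as cm


@pytest.fixture(scope="session")
def helix20():
    return cm.make_toy_protein(cm.ToyProteinSpec(20, "helix", seed=1))


@pytest.fixture(scope="session")
def hairpin20():
    return cm.make_toy_protein(cm.ToyProteinSpec(20, "hairpin", seed=2))


@pytest.fixture(scope="session")
def coil10():
    return cm.make_toy_protein(cm.ToyProteinSpec(10, "coil", seed=3))


@pytest.fixture(scope="session")
def small_np():
    """Reduced NP (3 nm, 150 beads) for engine-scale tests."""
    return cm.build_gold_np(30.0, 150, -0.5)


@pytest.fixture(scope="session")
def reference_np():
    """The 15 nm, 5160-bead, −0.5 e/bead particle."""
    return cm.build_gold_np(150.0, 5160, -0.5)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  LYS A   2       4.800   1.200   0.500  1.00  0.00           C
ATOM      5  CA  ASP A   3       8.100   2.600   1.100  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CA  ALA A   2      12.800   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       5.000   5.000   5.000  0.50  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb():
    return MINIMAL_PDB


@pytest.fixture
def two_model_pdb():
    return TWO_MODEL_PDB


@pytest.fixture
def altloc_pdb():
    return ALTLOC_PDB


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
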