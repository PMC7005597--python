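import numpy as np
import pytest

from glowdock.fixtures import generate_toy_complex, generate_toy_scoring_table
from glowdock.restraints import compute_true_interface


@pytest.fixture(scope="session")
def toy_complex():
    return generate_toy_complex(seed=1)


@pytest.fixture(scope="session")
def toy_table(toy_complex):
    return generate_toy_scoring_table(seed=1, complex_=toy_complex)


@pytest.fixture(scope="session")
def true_interface(toy_complex):
    return compute_true_interface(toy_complex.receptor, toy_complex.ligand)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


PDB_5_ATOMS = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.000   2.000   3.500  1.00  0.00           C
ATOM      4  O   ALA A   1       3.500   1.000   3.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000   4.000   3.200  1.00  0.00           C
END
"""


@pytest.fixture()
def five_atom_pdb(tmp_path):
    path = tmp_path / "five.pdb"
    path.write_text(PDB_5_ATOMS)
    return path
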