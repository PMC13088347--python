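import numpy as np
import pytest

from psforge.sequences import CANONICAL_AA, ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence(rng):
    def make(length: int = 50, seq_id: str = "rand") -> ProteinSequence:
        letters = rng.choice(list(CANONICAL_AA), size=length)
        return ProteinSequence(id=seq_id, residues="".join(letters))

    return make


# hand-written PDB fixtures -------------------------------------------------

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       0.000   0.000   5.000  1.00  0.00           C
ATOM      4  CA  SER A   3       0.000   0.000  12.000  1.00  0.00           C
END
"""

MISSING_CA_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       1.000   0.000   3.000  1.00  0.00           N
ATOM      3  CA  SER A   3       0.000   0.000   7.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       0.000   0.000   5.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    def write(content: str, name: str = "fixture.pdb"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return write
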