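import numpy as np
import pytest

from fapocket import CageSpec, DetectionParams, detect_pockets, make_cage
from fapocket.curation import dataset_from_structures
from fapocket.synthetic import negative_cage_spec, positive_cage_spec

TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      10.729   6.859  -4.209  1.00 10.00           C
ATOM      4  O   ALA A   1       9.580   7.190  -4.506  1.00 10.00           O
ATOM      5  CB  ALA A   1      11.751   4.625  -4.661  1.00 10.00           C
END
"""

LIGAND_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      10.729   6.859  -4.209  1.00 10.00           C
HETATM    4  C1  PLM A 201       0.000   0.000   0.000  1.00 10.00           C
HETATM    5  C2  PLM A 201       1.500   0.000   0.000  1.00 10.00           C
HETATM    6  O   HOH A 301       5.000   5.000   5.000  1.00 10.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.40 10.00           C
ATOM      3  CA BALA A   1      12.000   6.100  -5.200  0.60 10.00           C
ATOM      4  C   ALA A   1      10.729   6.859  -4.209  1.00 10.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def ligand_pdb(tmp_path):
    path = tmp_path / "ligand.pdb"
    path.write_text(LIGAND_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture(scope="session")
def canonical_cage():
    """The reference cavity cage: 200 all-carbon atoms, cavity radius 5 Å."""
    return make_cage(CageSpec(
        n_shell_atoms=200, shell_radius=9.0, cavity_radius=5.0,
        mouth_half_angle=15.0, element_mix=(("C", 1.0),), seed=1,
    ))


@pytest.fixture(scope="session")
def canonical_pockets(canonical_cage):
    return detect_pockets(canonical_cage, DetectionParams())


@pytest.fixture(scope="session")
def small_cage_dataset():
    """Pocket dataset from 10 acyl-cage positives + 10 ring/apo negatives."""
    entries = [(make_cage(positive_cage_spec(100 + s)), 1) for s in range(10)]
    entries += [
        (make_cage(negative_cage_spec(200 + s, "ring" if s % 2 == 0 else "none")), 0)
        for s in range(10)
    ]
    X, y, provenance = dataset_from_structures(entries)
    return X, y, provenance
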