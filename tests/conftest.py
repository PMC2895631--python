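import numpy as np
import pytest

from crowdshift.structure import AtomisticStructure


def make_structure(coords, radii=None, masses=None, elements=None,
                   res_ids=None, chain_ids=None, label=""):
    """Hand-rolled structure for geometric tests."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    radii = np.full(n, 1.7) if radii is None else np.asarray(radii, float)
    masses = np.full(n, 12.011) if masses is None else np.asarray(masses, float)
    elements = np.array(["C"] * n, object) if elements is None else np.asarray(elements, object)
    res_ids = np.arange(1, n + 1) if res_ids is None else np.asarray(res_ids, int)
    chain_ids = np.array(["A"] * n, object) if chain_ids is None else np.asarray(chain_ids, object)
    return AtomisticStructure(
        elements=elements,
        coords=coords,
        radii=radii,
        masses=masses,
        chain_ids=chain_ids,
        res_ids=res_ids,
        res_names=np.array(["RES"] * n, object),
        atom_names=np.array([f"C{i+1}" for i in range(n)], object),
        label=label,
    )


@pytest.fixture
def single_atom():
    return make_structure([[0.0, 0.0, 0.0]], radii=[1.9])


@pytest.fixture
def point_probe():
    return make_structure([[0.0, 0.0, 0.0]], radii=[1e-12])


TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  O   HOH A  99      60.000  60.000  60.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       1.100   2.100   3.100  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.600   2.100   3.100  1.00  0.00           C
ENDMDL
END
"""
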