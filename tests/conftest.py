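import numpy as np
import pytest

from spinsight import LabelConformer, LabelSite, RotamerEnsemble, make_toy_structure
from spinsight.structure import Atom, Structure

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def exposed_helix():
    return make_toy_structure("exposed-helix", seed=0)


@pytest.fixture(scope="session")
def two_site_scaffold():
    return make_toy_structure("two-site-scaffold", seed=0)


def make_atom(name, resname, chain, resnum, pos, element=None, serial=1):
    return Atom(
        serial=serial,
        name=name,
        residue_name=resname,
        chain=chain,
        residue_number=resnum,
        position=np.asarray(pos, float),
        element=element or name[0],
    )


def point_ensemble(midpoints, site=("A", 1), seed=0):
    """Ensemble whose conformers are collapsed to given paramagnetic centers."""
    confs = []
    for m in midpoints:
        m = np.asarray(m, float)
        confs.append(
            LabelConformer(
                atom_names=("N1", "O1"),
                atom_positions=np.array([m, m]),
                no_midpoint=m,
            )
        )
    return RotamerEnsemble(
        site=LabelSite(*site),
        conformers=confs,
        n_requested=len(confs),
        seed=seed,
        n_attempted=len(confs),
    )


def leucine_like_structure():
    """One residue with a full side chain plus a neighbour, for substitution tests."""
    atoms = [
        make_atom("N", "LEU", "A", 5, (0, 0, 0), "N", 1),
        make_atom("CA", "LEU", "A", 5, (1.458, 0, 0), "C", 2),
        make_atom("C", "LEU", "A", 5, (2.0, 1.4, 0), "C", 3),
        make_atom("O", "LEU", "A", 5, (3.2, 1.5, 0), "O", 4),
        make_atom("CB", "LEU", "A", 5, (2.0, -0.8, 1.2), "C", 5),
        make_atom("CG", "LEU", "A", 5, (2.1, -2.3, 1.2), "C", 6),
        make_atom("CD1", "LEU", "A", 5, (2.8, -2.8, 2.4), "C", 7),
        make_atom("CD2", "LEU", "A", 5, (0.8, -3.0, 1.0), "C", 8),
        make_atom("N", "GLY", "A", 6, (1.6, 2.5, 0), "N", 9),
        make_atom("CA", "GLY", "A", 6, (2.2, 3.8, 0), "C", 10),
        make_atom("C", "GLY", "A", 6, (3.7, 3.8, 0), "C", 11),
    ]
    return Structure(atoms=atoms, identifier="leu-toy")
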