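import numpy as np
import pytest

from multiconf.bench import make_toy_system
from multiconf.density import DensityGrid, ScatteringMode
from multiconf.peptide import build_peptide
from multiconf.structure import Atom, Conformer, Residue, Structure


@pytest.fixture(scope="session")
def toy_peptide() -> Structure:
    """Five-residue ideal-geometry peptide covering the common side chains."""
    return build_peptide(["SER", "VAL", "LEU", "TYR", "THR"])


@pytest.fixture(scope="session")
def toy_multiconf() -> Structure:
    """Ground-truth toy with two-rotamer residues at 0.6/0.4."""
    return make_toy_system(8, 0.25, seed=3)


@pytest.fixture()
def small_grid() -> DensityGrid:
    return DensityGrid(np.zeros((12, 12, 12), dtype=np.float32),
                       np.full(3, 0.5), np.zeros(3))


@pytest.fixture()
def xray_mode() -> ScatteringMode:
    return ScatteringMode("xray")


@pytest.fixture()
def em_mode() -> ScatteringMode:
    return ScatteringMode("em")


def single_atom_conformer(pos=(3.0, 3.0, 3.0), b=15.0, occ=1.0,
                          element="C", name="CA") -> Conformer:
    return Conformer("", [Atom(name, np.array(pos, dtype=float), b, occ,
                               element)], occ)


def wrap_residue(conformers, name="ALA", seqnum=1) -> Residue:
    return Residue("A", seqnum, "", name, list(conformers))
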