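import numpy as np
import pytest

from chitofib.core import FibrilTopology, Structure
from chitofib.crystal import CHITOSAN_CELL, FibrilSpec, build_fibril


@pytest.fixture(scope="session")
def small_fibril():
    """4 sheets x 2 chains x 8 residues: cheap but has interior sheets."""
    spec = FibrilSpec(n_sheets=4, chains_per_sheet=2, degree_of_polymerization=8)
    structure, topology = build_fibril(CHITOSAN_CELL, spec=spec)
    return structure, topology, spec


@pytest.fixture(scope="session")
def default_fibril():
    """The full default fibril: 4 sheets x 6 chains x 20 residues."""
    spec = FibrilSpec()
    structure, topology = build_fibril(CHITOSAN_CELL, spec=spec)
    return structure, topology, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def single_chain_topology(n_residues=2, chain="A"):
    return FibrilTopology(
        chain_to_sheet={chain: 1},
        chain_direction={chain: 1},
        n_sheets=1,
        chains_per_sheet=1,
        degree_of_polymerization=n_residues,
    )


def make_structure(atoms, box=None):
    """Build a Structure from (name, element, resname, resindex, chain, xyz) rows."""
    return Structure(
        atom_name=np.array([a[0] for a in atoms]),
        element=np.array([a[1] for a in atoms]),
        res_name=np.array([a[2] for a in atoms]),
        res_index=np.array([a[3] for a in atoms], dtype=np.int64),
        chain_id=np.array([a[4] for a in atoms]),
        coords=np.array([a[5] for a in atoms], dtype=float),
        box=box,
    )
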