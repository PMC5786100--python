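import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from glycoccs.ensemble import AtomRecord, ConformerEnsemble
from glycoccs.gas import load_gas


@pytest.fixture(scope="session")
def helium():
    return load_gas("He", temperature=300.0)


@pytest.fixture(scope="session")
def nitrogen():
    return load_gas("N2", temperature=300.0)


def bead_chain(n: int = 5, spacing: float = 2.5, element: str = "C") -> ConformerEnsemble:
    """A gently bent single-conformer bead chain (non-collinear)."""
    t = np.arange(n, dtype=float)
    coords = np.column_stack([spacing * t, 0.8 * np.sin(0.9 * t), 0.3 * t ** 1.2])
    atoms = [AtomRecord(i, element, element, residue_index=i + 1) for i in range(n)]
    return ConformerEnsemble(atoms, coords[None, :, :])


@pytest.fixture
def chain5() -> ConformerEnsemble:
    return bead_chain(5)
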