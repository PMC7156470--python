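import numpy as np
import pytest

from ioncage.ionization_rates import RateTable
from ioncage.synthetic_data import SimCell, generate_supercell


@pytest.fixture(scope="session")
def rates():
    return RateTable.default()


@pytest.fixture(scope="session")
def supercell():
    """The default 14 Å / 300-atom solvated-protein fixture."""
    return generate_supercell(seed=1)


@pytest.fixture()
def ss_pair():
    """Isolated S-S pair at the disulfide bond length, in vacuum."""
    return SimCell(
        edge_length=np.inf,
        periodic=False,
        elements=["S", "S"],
        positions=[[-1.04, 0.0, 0.0], [1.04, 0.0, 0.0]],
        bridge=(0, 1),
    )
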