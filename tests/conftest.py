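import numpy as np
import pytest

from targetkit import DoseResponseTable
from targetkit.datasets import DOSE_GRID_GY


def exponential_table(d37: float, group_id: str = "g", grid=DOSE_GRID_GY) -> DoseResponseTable:
    """Noiseless single-hit table: rate = exp(-D/d37) on the standard grid."""
    doses = np.asarray(grid, dtype=float)
    return DoseResponseTable(group_id=group_id, doses=doses, rates=np.exp(-doses / d37))


@pytest.fixture
def dose_grid():
    return np.asarray(DOSE_GRID_GY, dtype=float)
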