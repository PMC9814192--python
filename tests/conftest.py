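import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from mamsleep.synthetic import CellGenParams, FlyGenParams, synth_cells, synth_dam


@pytest.fixture(scope="session")
def small_cell_batch():
    """A small batch of default-condition synthetic cells with truth."""
    return synth_cells(CellGenParams(n_cells=6, seed=11))


@pytest.fixture(scope="session")
def one_cell(small_cell_batch):
    cells, _ = small_cell_batch
    return cells[0]


@pytest.fixture(scope="session")
def fly_batch():
    """A small cohort with an enforced-wake night on day 4 of 6."""
    return synth_dam(FlyGenParams(n_flies=8, n_days=6, sd_night=4, seed=5))
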