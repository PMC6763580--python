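import numpy as np
import pytest

from adjclust.io_prep import CellTable, MarkerPanel


@pytest.fixture
def panel3() -> MarkerPanel:
    return MarkerPanel(marker_names=("CD3", "CD4", "CD8"), weights=(1.0, 2.0, 0.5))


@pytest.fixture
def small_table(panel3) -> CellTable:
    rng = np.random.default_rng(7)
    values = rng.gamma(2.0, 20.0, size=(50, 3))
    return CellTable(
        values=values,
        marker_names=panel3.marker_names,
        sample_id=np.full(50, "s1", dtype=object),
    )
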