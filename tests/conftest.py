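import numpy as np
import pandas as pd
import pytest

from peatmethane.community import OTUTable


@pytest.fixture
def tiny_table() -> OTUTable:
    """3 taxa x 2 samples literal fixture."""
    return OTUTable(
        pd.DataFrame(
            [[5, 0], [3, 2], [2, 8]],
            index=["OTU1", "OTU2", "OTU3"],
            columns=["S1", "S2"],
        )
    )


@pytest.fixture
def small_table() -> OTUTable:
    """Deterministic 12-taxa x 8-sample table with varied depths."""
    rng = np.random.default_rng(1234)
    counts = rng.negative_binomial(2, 0.05, size=(12, 8))
    counts[0] += 50  # a ubiquitous taxon
    return OTUTable(
        pd.DataFrame(
            counts,
            index=[f"OTU{i}" for i in range(12)],
            columns=[f"S{j}" for j in range(8)],
        )
    )
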