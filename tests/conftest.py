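import numpy as np
import pandas as pd
import pytest

from kymoxl import QuantTable


@pytest.fixture
def tiny_quant_table():
    """Hand-built two-condition table: 3 pairs, 2 runs per condition."""
    intensities = pd.DataFrame(
        {
            "A_r1": [100.0, 50.0, 10.0],
            "A_r2": [110.0, 55.0, 12.0],
            "B_r1": [100.0, 200.0, np.nan],
            "B_r2": [105.0, 210.0, np.nan],
        },
        index=["p1", "p2", "p3"],
    )
    runs = pd.DataFrame(
        {
            "run_id": ["A_r1", "A_r2", "B_r1", "B_r2"],
            "condition": ["A", "A", "B", "B"],
            "reaction": ["a1", "a2", "b1", "b2"],
            "injection": [1, 1, 1, 1],
        }
    )
    totals = pd.Series({"A_r1": 1000.0, "A_r2": 1000.0, "B_r1": 1000.0, "B_r2": 1000.0})
    return QuantTable(intensities, runs, totals)
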