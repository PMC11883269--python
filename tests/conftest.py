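import numpy as np
import pandas as pd
import pytest

from meristemsim.lineage import LineageTable
from meristemsim.params import ModelParams
from meristemsim.synth import SynthConfig, generate_lineage_table


@pytest.fixture(scope="session")
def default_synth():
    """Default generator output: five founders, Phase I/II, antheridia."""
    return generate_lineage_table(SynthConfig(seed=7))


@pytest.fixture()
def tiny_params():
    return ModelParams(t_end=12.0, dt=0.05)


def make_table(rows):
    """Build a LineageTable from (nucleus, t, lineage, layer, antheridium, parent)."""
    frame = pd.DataFrame(
        [
            {
                "nucleus_id": n,
                "time_h": float(t),
                "x_px": 10.0,
                "y_px": 10.0,
                "lineage_id": lin,
                "layer": layer,
                "is_antheridium": anth,
                "parent_id": parent,
            }
            for (n, t, lin, layer, anth, parent) in rows
        ]
    )
    return LineageTable(frame)


@pytest.fixture()
def simple_division_table():
    """One founder dividing at (6, 12], one daughter dividing at (12, 18]."""
    rows = [
        ("a", 0, "L1", "outer", False, None),
        ("a", 6, "L1", "outer", False, None),
        ("b", 12, "L1", "outer", False, "a"),
        ("c", 12, "L1", "inner", False, "a"),
        ("b", 18, "L1", "outer", False, None),
        ("d", 18, "L1", "inner", False, "c"),
        ("e", 18, "L1", "inner", False, "c"),
    ]
    return make_table(rows)
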