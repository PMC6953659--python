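import numpy as np
import pytest

import surveygap as sg


@pytest.fixture(scope="session")
def small_dataset():
    """One 20x20 synthetic study shared by read-only tests."""
    cfg = sg.SimConfig(grid_rows=20, grid_cols=20, n_species=60, seed=42)
    return sg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_cell_table(small_dataset):
    table, dropped = sg.assign_records(small_dataset["records"], small_dataset["grid"])
    assert dropped == {"outside_grid": 0, "non_land": 0}
    return table


def moran_i(values: np.ndarray, graph) -> float:
    """Brute-force Moran's I over an adjacency graph (oracle)."""
    z = values - values.mean()
    num = 0.0
    w = 0
    for i, j in graph.edges:
        num += 2 * z[i] * z[j]  # symmetric pairs
        w += 2
    return (len(values) / w) * num / float(z @ z)
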