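import numpy as np
import pandas as pd
import pytest

from nichetrace.simdata import SimConfig, default_cnv_panel, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """One modest tissue shared by read-only tests."""
    cfg = SimConfig(seed=11, n_lesions=4, cells_per_lesion=(80, 120),
                    stroma_density=500, fov=(1200, 1200))
    return generate_tissue(cfg)


@pytest.fixture(scope="session")
def cnv_panel():
    return default_cnv_panel(n_chromosomes=4)


def make_cells(xy, compartment="epithelial", state=None, sample="s0",
               condition="ctrl"):
    """Minimal hand-built cell table from an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "sample": sample,
            "condition": condition,
            "compartment": compartment,
            "state": state if state is not None else compartment,
        }
    )
    return df.set_index("cell_id", drop=False)
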