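import numpy as np
import pandas as pd
import pytest

from immunosig.core import SCALE_LOG2, SCALE_RAW, ExpressionMatrix, StudyDesign
from immunosig.simulate import CellModule, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_log2():
    """4 genes x 4 samples log2 matrix with two groups of two."""
    data = pd.DataFrame(
        {
            "A1": [1.0, 0.0, 5.0, 2.0],
            "A2": [1.0, 2.0, 5.5, 2.0],
            "B1": [1.0, 3.0, 1.0, 2.0],
            "B2": [1.0, 5.0, 1.5, 2.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(data, SCALE_LOG2)


@pytest.fixture
def toy_design():
    return StudyDesign.from_mapping(
        {"A1": "ctl", "A2": "ctl", "B1": "trt", "B2": "trt"}, reference="ctl"
    )


@pytest.fixture
def small_sim_config():
    """Down-scaled simulation used where many replicates are drawn."""
    return SimulationConfig(
        n_genes=300,
        n_control=4,
        n_treated=4,
        modules=(
            CellModule("PC", 20, 0.05, 0.2),
            CellModule("B", 20, 0.30, 0.6),
        ),
        n_direct=20,
        seed=11,
    )


def random_log2_matrix(rng, p=50, n=8):
    data = pd.DataFrame(
        rng.normal(6, 2, (p, n)),
        index=[f"g{i}" for i in range(p)],
        columns=[f"s{j}" for j in range(n)],
    )
    return ExpressionMatrix(data, SCALE_LOG2)
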