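import numpy as np
import pandas as pd
import pytest

from renalclass import ExpressionMatrix, SimulationConfig, simulate_cn, simulate_expression


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic expression study, shared across tests."""
    config = SimulationConfig()
    tumors, normals, annotation, truth = simulate_expression(config, seed=11)
    return {
        "config": config,
        "tumors": tumors,
        "normals": normals,
        "annotation": annotation,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_cn_sim():
    config = SimulationConfig()
    cn, annotation, truth = simulate_cn(config, seed=11)
    return {"config": config, "cn": cn, "annotation": annotation, "truth": truth}


@pytest.fixture()
def small_matrix():
    """A tiny labeled expression matrix for hand-checkable computations."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(10, 8)),
        index=[f"p{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(8)],
    )
    labels = pd.Series(["A"] * 4 + ["B"] * 4, index=values.columns)
    return ExpressionMatrix(values, labels)
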