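import numpy as np
import pandas as pd
import pytest

from metapart.census import CommunityMatrix, TreeRecord


@pytest.fixture
def tiny_records():
    """Seven stems over two plots and three species; one below the 10-cm cut."""
    return [
        TreeRecord("P1", "A", 12.0, 10.0),
        TreeRecord("P1", "A", 20.0, 15.0),
        TreeRecord("P1", "A", 35.2, 22.0),
        TreeRecord("P1", "B", 10.0, 8.0),
        TreeRecord("P2", "B", 15.0, 12.0),
        TreeRecord("P2", "C", 9.9, 7.0),
        TreeRecord("P2", "C", 11.0, 9.0),
    ]


def make_matrix(rows, plot_ids=None, species_ids=None, basis="abundance"):
    arr = np.asarray(rows, dtype=float)
    plot_ids = plot_ids or [f"P{i + 1}" for i in range(arr.shape[0])]
    species_ids = species_ids or [chr(ord("A") + j) for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=pd.Index(plot_ids, name="plot_id"), columns=species_ids)
    return CommunityMatrix(df, basis=basis)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def sorting_scenario():
    """One species-sorting synthetic dataset at the default dimensions."""
    from metapart.synth import ScenarioConfig, generate_scenario

    return generate_scenario(ScenarioConfig(archetype="species_sorting", seed=2024))
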