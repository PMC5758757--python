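import numpy as np
import pandas as pd
import pytest

from hridaya.core import EnsembleConfig
from hridaya.io import FeatureTable, GeneSets
from hridaya.simulate import SimulationConfig, gen_feature_table


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Small planted two-layer study used across module tests."""
    return SimulationConfig(
        seed=11,
        n_genes=400,
        n_features=40,
        n_disease_positives=50,
        n_dcm_positives=12,
        missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    table, sets, truth = gen_feature_table(small_cfg)
    return table, sets, truth


@pytest.fixture(scope="session")
def fast_config() -> EnsembleConfig:
    """Logistic base classifier with few iterations, for simulation-heavy tests."""
    return EnsembleConfig(n_iterations=10, base_classifier="logistic", seed=7)


@pytest.fixture()
def tiny_table() -> FeatureTable:
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(20)]
    df = pd.DataFrame(
        rng.standard_normal((20, 3)),
        index=genes,
        columns=["genetic_0", "transcriptomic_1", "evolutionary_2"],
    )
    cats = {
        "genetic_0": "genetic",
        "transcriptomic_1": "transcriptomic",
        "evolutionary_2": "evolutionary",
    }
    return FeatureTable(df, cats)


@pytest.fixture()
def tiny_sets(tiny_table) -> GeneSets:
    genes = list(tiny_table.entity_ids)
    return GeneSets(frozenset(genes[:8]), frozenset(genes[:3]), frozenset(genes))
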