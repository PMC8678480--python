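import numpy as np
import pandas as pd
import pytest

from ceranet import ExpressionMatrix, GroupDesign, SimulationConfig, simulate_all


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 features x 4 samples, one feature per RNA class."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 6.0, 7.0]],
        index=["G1", "L1", "M1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, pd.Series(["mRNA", "lncRNA", "miRNA"], index=values.index))


@pytest.fixture
def design4() -> GroupDesign:
    return GroupDesign(
        pd.Series(["case", "case", "control", "control"], index=["s1", "s2", "s3", "s4"])
    )


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced feature counts for fast unit tests; effect sizes unchanged."""
    base = dict(
        seed=seed,
        n_mrna=120,
        n_lncrna=100,
        n_mirna=30,
        n_planted_de_mrna=10,
        n_planted_de_lncrna=10,
        n_planted_de_mirna=3,
        n_planted_triplets=6,
        n_decoy_interactions=40,
        n_decoy_tfs=10,
        n_extra_immune_genes=20,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_sim():
    """One full simulation at generator defaults, shared across tests."""
    return simulate_all(SimulationConfig(seed=42))


def group_masks(design: GroupDesign, sample_ids):
    case = [s for s in sample_ids if design.groups[s] == "case"]
    ctrl = [s for s in sample_ids if design.groups[s] == "control"]
    return case, ctrl
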