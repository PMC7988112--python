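import numpy as np
import pandas as pd
import pytest

from adsigkit.io_model import ExpressionMatrix
from adsigkit.synthetic_data import (HumanSimConfig, MouseSimConfig,
                                     SimulationConfig, ValidationSimConfig)


@pytest.fixture
def tiny_log_matrix():
    """4 genes x 6 samples of log2 intensities with two groups."""
    rng = np.random.default_rng(0)
    genes = ["GA", "GB", "GC", "GD"]
    samples = [f"s{i}" for i in range(6)]
    vals = pd.DataFrame(rng.normal(8, 1, (4, 6)), index=genes, columns=samples)
    ann = pd.DataFrame({"group": ["ctrl"] * 3 + ["case"] * 3}, index=samples)
    return ExpressionMatrix(vals, "log_intensity", ann)


def small_study_config():
    """A scaled-down study used where only structure matters, not power."""
    return SimulationConfig(
        n_genes=300, n_pathways=10, pathway_size_range=(5, 30),
        n_ambiguous_orthologs=5,
        mouse=MouseSimConfig(n_shared_per_direction=10, n_model_specific=10,
                             n_discordant=4, n_low_expressed=30),
        human=HumanSimConfig(n_signature_per_direction=5,
                             n_human_only_per_direction=8),
        validation=ValidationSimConfig(n_subjects=10),
        seed=17,
    )


@pytest.fixture
def small_sim_config():
    return small_study_config()


def make_counts(values, groups, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    ann = pd.DataFrame({"group": groups}, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            "counts", ann)


def make_log_matrix(values, groups, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    ann = pd.DataFrame({"group": groups}, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            "log_intensity", ann)
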