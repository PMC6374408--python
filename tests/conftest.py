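import dataclasses

import numpy as np
import pandas as pd
import pytest

from coexcand import ExpressionMatrix, SimulationConfig


@pytest.fixture(scope="session")
def recovery_config() -> SimulationConfig:
    """Planted-module recovery settings: a 30-gene module, 15 known guides,
    and 20 planted DEGs concentrated (75%) inside the module."""
    return SimulationConfig(n_deg=20, frac_deg_in_pathway=0.75)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, fully featured simulation for pipeline-level tests."""
    return SimulationConfig(
        n_genes=400,
        n_pathway=15,
        n_guides=8,
        p_within=0.7,
        p_background=0.01,
        n_deg=12,
        frac_deg_in_pathway=0.5,
    )


def make_matrix(case_log2, control_log2, genes=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-gene lists of log2 FPKM replicates."""
    case_log2 = np.atleast_2d(np.asarray(case_log2, dtype=float))
    control_log2 = np.atleast_2d(np.asarray(control_log2, dtype=float))
    n_genes, r = case_log2.shape
    if genes is None:
        genes = [f"g{i}" for i in range(1, n_genes + 1)]
    samples = [f"high_{k}" for k in range(1, r + 1)] + [
        f"low_{k}" for k in range(1, control_log2.shape[1] + 1)
    ]
    values = pd.DataFrame(
        np.hstack([2.0 ** case_log2, 2.0 ** control_log2]),
        index=genes,
        columns=samples,
    )
    design = pd.DataFrame(
        {
            "genotype": ["high"] * case_log2.shape[1] + ["low"] * control_log2.shape[1],
            "replicate": list(range(1, case_log2.shape[1] + 1))
            + list(range(1, control_log2.shape[1] + 1)),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(values, design)


@pytest.fixture
def matrix_factory():
    return make_matrix
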