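import numpy as np
import pandas as pd
import pytest

from pemtscope.io import ClinicalTable, ExpressionMatrix, GeneSet
from pemtscope.simulate import SimulationConfig, signature_genes, simulate_cohort


def expr_from_array(arr, gene_prefix="g", sample_prefix="s", scale="linear"):
    arr = np.asarray(arr, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(arr.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), scale=scale)


@pytest.fixture
def toy_expr():
    rng = np.random.default_rng(7)
    return expr_from_array(rng.uniform(0, 100, size=(40, 6)))


@pytest.fixture
def toy_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "time": [5.0, 12.0, 20.0, 3.5],
                "event": [1, 0, 1, 1],
                "nodal": pd.Categorical(["N+", "N0", "N+", "N0"]),
            },
            index=["s0", "s1", "s2", "s3"],
        )
    )


@pytest.fixture(scope="session")
def contaminated_cohort():
    """One contaminated synthetic cohort plus its signature gene set."""
    cfg = SimulationConfig(
        n_samples=150, n_genes=800, caf_signature_strength=4.0, seed=12
    )
    expr, clinical, truth = simulate_cohort(cfg)
    gs = GeneSet("sig", signature_genes(cfg))
    return cfg, expr, clinical, truth, gs


@pytest.fixture(scope="session")
def clean_cohort():
    """Uncontaminated cohort with survival linked to activity."""
    cfg = SimulationConfig(n_samples=200, n_genes=600, caf_signature_strength=0.0, seed=5)
    expr, clinical, truth = simulate_cohort(cfg)
    gs = GeneSet("sig", signature_genes(cfg))
    return cfg, expr, clinical, truth, gs
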