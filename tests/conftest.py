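import numpy as np
import pandas as pd
import pytest

import lungssp as L


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic development cohort, background-corrected, with labels."""
    matrix, labels, truth = L.simulate_histology_cohort(L.SimulationConfig(seed=11))
    neg = [g for g in matrix.gene_ids if g.startswith("NEG_")]
    corrected = L.background_correct(matrix, neg)
    return corrected, labels, truth


@pytest.fixture(scope="session")
def model(cohort):
    matrix, labels, _ = cohort
    return L.train_ssp(matrix, labels, config=L.TrainConfig(seed=7))


@pytest.fixture(scope="session")
def fusion_cohort():
    config = L.FusionSimulationConfig(seed=3)
    matrix, truth = L.simulate_fusion_probes(config)
    return matrix, truth


def random_expression(rng: np.random.Generator, n_genes=11, n_samples=8, panel=None):
    """Random positive matrix over the default panel genes (distinct values per sample)."""
    panel = panel or L.default_marker_panel()
    genes = list(panel.genes)[:n_genes]
    vals = rng.uniform(1.0, 1000.0, size=(len(genes), n_samples))
    df = pd.DataFrame(vals, index=genes, columns=[f"s{i}" for i in range(n_samples)])
    return L.ExpressionMatrix(df)
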