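import numpy as np
import pandas as pd
import pytest

import coexmark as cm


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across the suite (seed fixed)."""
    return cm.generate_cohort(cm.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def consensus(cohort):
    return cm.consensus_network(cohort.tissue_a, cohort.tissue_b,
                                cohort.background, threshold=0.8)


def make_dataset(values, labels=None, name="toy"):
    """Small helper: ExpressionDataset from a dict/array."""
    df = pd.DataFrame(values)
    lab = pd.Series(labels, index=df.columns) if labels is not None else None
    return cm.ExpressionDataset(df, lab, name=name)


def random_dataset(rng, n_genes=20, n_samples=30, name="random"):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    values = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                          index=genes, columns=samples)
    half = n_samples // 2
    labels = pd.Series(["control"] * half + ["tumor"] * (n_samples - half),
                       index=samples)
    return cm.ExpressionDataset(values, labels, name=name)
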