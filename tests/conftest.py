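"""Shared fixtures: small random expression panels and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mgca.io import ExpressionMatrix, GeneFeatureTable, GeneSet
from mgca.synthetic import ModuleSpec, SyntheticSpec, generate


def random_expression(n_genes: int, n_samples: int, seed: int) -> ExpressionMatrix:
    """Positive random matrix with generic metadata, for oracle tests."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=1.0, sigma=0.6, size=(n_genes, n_samples))
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{j:02d}" for j in range(n_samples)],
            "region": [f"R{j % 2 + 1}" for j in range(n_samples)],
            "stage": [f"S{j % 4 + 1}" for j in range(n_samples)],
            "sex": ["M" if j % 2 else "F" for j in range(n_samples)],
        }
    )
    return ExpressionMatrix(gene_ids, vals, samples)


def features_for(matrix: ExpressionMatrix, seed: int) -> GeneFeatureTable:
    rng = np.random.default_rng(seed + 1)
    n = matrix.n_genes
    return GeneFeatureTable.from_columns(
        matrix.gene_ids,
        abundance=matrix.values.mean(axis=1),
        gdna_size=np.round(rng.lognormal(np.log(2e4), 1.0, n)) + 200,
        gc_content=rng.uniform(30, 70, n),
    )


@pytest.fixture(scope="session")
def panel_50x20():
    """50-gene x 20-sample random panel with features (oracle fixture)."""
    matrix = random_expression(50, 20, seed=101)
    return matrix, features_for(matrix, seed=101)


@pytest.fixture(scope="session")
def small_synthetic():
    """Module-free synthetic dataset at reduced scale."""
    return generate(SyntheticSpec(n_genes=400, n_regions=2, n_stages=4, seed=21))


@pytest.fixture(scope="session")
def module_synthetic():
    """Synthetic dataset with one planted 40-gene module and its decoys."""
    spec = SyntheticSpec(
        n_genes=600,
        seed=31,
        modules=(ModuleSpec(size=40, target_cc=0.5),),
    )
    return generate(spec)


def toy_six_gene_model():
    """Deterministic 6-gene instance whose matched-set tree is enumerable.

    Genes t1..t6 are ranked 1..6 by abundance; the seed set {t2, t5} with
    window 1 gives disjoint candidate pools {t1, t3} and {t4, t6}.
    """
    from mgca.model import MGCA

    rng = np.random.default_rng(5)
    vals = rng.lognormal(1.0, 0.7, size=(6, 8))
    gene_ids = [f"t{i}" for i in range(1, 7)]
    samples = pd.DataFrame({"sample_id": [f"s{j}" for j in range(8)]})
    matrix = ExpressionMatrix(gene_ids, vals, samples)
    features = GeneFeatureTable.from_columns(
        gene_ids,
        abundance=np.arange(1.0, 7.0),
        gdna_size=np.arange(1000.0, 7000.0, 1000.0),
        gc_content=np.arange(35.0, 65.0, 5.0),
    )
    seed = GeneSet("toy-seed", ["t2", "t5"])
    return MGCA(matrix, seed, features, window=1, filter_abundance=False,
                recompute_abundance=False)
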