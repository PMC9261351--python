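"""Shared fixtures: tiny hand-built contrast tables and a small simulated
study with planted structure."""

import numpy as np
import pandas as pd
import pytest

from consensome import ContrastTable, SimConfig, gene_universe, simulate_compendium


def make_contrast(contrast_id, genes, log2fc, pvalue, assayed=None):
    n = len(genes)
    return ContrastTable(
        contrast_id,
        pd.DataFrame(
            {
                "gene_id": list(genes),
                "log2fc": np.asarray(log2fc, dtype=float),
                "pvalue": np.asarray(pvalue, dtype=float),
                "assayed": np.ones(n, dtype=bool)
                if assayed is None
                else np.asarray(assayed, dtype=bool),
            }
        ),
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genes=400, n_contrasts=5, frac_true=0.05, seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    compendium, truth = simulate_compendium(small_cfg)
    return small_cfg, compendium, truth


@pytest.fixture(scope="session")
def small_universe(small_cfg):
    return gene_universe(small_cfg.n_genes)
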