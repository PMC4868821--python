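"""Shared fixtures: one session-scoped synthetic experiment plus tiny
hand-built datasets for arithmetic-level tests."""

import numpy as np
import pandas as pd
import pytest

from embryolin.allelic import classify_table
from embryolin.datasets import ExpressionDataset
from embryolin.simulate import SimConfig, simulate_experiment
from embryolin.variability import fit_noise_from_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One full five-day experiment under the default study conditions."""
    return simulate_experiment(SimConfig(seed=2))


@pytest.fixture(scope="session")
def sim_dataset(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def sim_alleles(default_sim):
    return default_sim[1]


@pytest.fixture(scope="session")
def sim_truth(default_sim):
    return default_sim[2]


@pytest.fixture(scope="session")
def sim_classified(sim_alleles):
    return classify_table(sim_alleles)


@pytest.fixture(scope="session")
def noise_fit(sim_dataset):
    return fit_noise_from_dataset(sim_dataset)


def build_dataset(values, chroms=None, days=None, sexes=None, embryos=None,
                  starts=None, spikein=None):
    """Hand-built ExpressionDataset from a genes × cells array."""
    values = np.asarray(values, float)
    n_g, n_c = values.shape
    gene_ids = [f"g{i}" for i in range(n_g)]
    cell_ids = [f"c{j}" for j in range(n_c)]
    genes = pd.DataFrame({
        "chrom": chroms if chroms is not None else ["chr1"] * n_g,
        "start": starts if starts is not None else np.arange(1, n_g + 1),
        "length_bp": 1000,
        "is_spikein": spikein if spikein is not None else [False] * n_g,
    }, index=pd.Index(gene_ids, name="gene_id"))
    cells = pd.DataFrame({
        "embryo_id": embryos if embryos is not None else ["e1"] * n_c,
        "day": days if days is not None else [5] * n_c,
        "subday": "",
        "sex": sexes if sexes is not None else ["unknown"] * n_c,
        "qc_pass": True,
    }, index=pd.Index(cell_ids, name="cell_id"))
    vals = pd.DataFrame(values, index=genes.index, columns=cells.index)
    return ExpressionDataset(vals, genes, cells)
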