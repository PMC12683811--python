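import numpy as np
import pytest

from cellsvg import pipeline, preprocessing, simulate


@pytest.fixture(scope="session")
def small_bin_sim():
    """A small bin-level dataset with clean geometry (no background scatter)."""
    config = simulate.SimulationConfig(
        n_cells=30, n_genes=20, seed=11, background_scatter=0.0
    )
    nuclei, types, counts, positions, truth, cell_totals = simulate.simulate_bin_dataset(config)
    return {
        "config": config,
        "nuclei": nuclei,
        "types": types,
        "counts": counts,
        "positions": positions,
        "truth": truth,
        "cell_totals": cell_totals,
    }


@pytest.fixture(scope="session")
def planted_adata():
    """A preprocessed cell-level dataset with planted types and SVGs."""
    config = simulate.study_conditions(n_cells=1200, n_genes=120, seed=7)
    adata = simulate.simulate_cell_dataset(config)
    flags = adata.uns["svg_flags"].copy()
    pconfig = pipeline.simulation_study_config(seed=0, n_genes=config.n_genes)
    adata = preprocessing.preprocess(adata, pconfig.seed, pconfig.clustering)
    adata.uns["svg_flags"] = flags
    return adata, pconfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)
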