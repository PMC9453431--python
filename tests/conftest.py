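import numpy as np
import pandas as pd
import pytest

import phenanchor as pa
from phenanchor.simulate import SimulationConfig, make_design, simulate_dataset


@pytest.fixture(scope="session")
def design32() -> pa.ExperimentDesign:
    """The canonical 8-concentration x 4-replicate layout."""
    return make_design((0.0, 0.205, 0.512, 1.28, 3.2, 8.0, 20.0, 50.0), 4)


@pytest.fixture(scope="session")
def small_dataset() -> pa.SyntheticDataset:
    """A compact synthetic dataset with all four gene classes."""
    return simulate_dataset(
        SimulationConfig(
            n_ahr_module=20, n_sensitive=10, n_high_only=10, n_null=60, seed=1
        )
    )


@pytest.fixture(scope="session")
def null_dataset() -> pa.SyntheticDataset:
    """All-null genes (no module correlation): the calibration substrate."""
    return simulate_dataset(
        SimulationConfig(
            n_ahr_module=0, n_sensitive=0, n_high_only=0, n_null=2000, seed=11
        )
    )


@pytest.fixture(scope="session")
def normalized_small(small_dataset):
    from phenanchor import dge

    filtered = dge.filter_low_counts(small_dataset.counts)
    return dge.normalize_counts(filtered)


@pytest.fixture(scope="session")
def loco_enrichment_counts():
    """Pooled 2x2 table over 5 seeds: planted-module vs other edges against
    the consistently-higher classification."""
    from phenanchor.dge import filter_low_counts, normalize_counts
    from phenanchor.loco import classify_edges, edge_weight_ratios, loco_networks, module_weight_matrix
    from phenanchor.network import NetworkConfig, fold_change_matrix, infer_network, select_top_cv

    table = np.zeros((2, 2), dtype=int)
    for seed in (2, 3, 4, 5, 6):
        ds = simulate_dataset(
            SimulationConfig(n_ahr_module=12, n_sensitive=4, n_high_only=4, n_null=20, seed=seed)
        )
        norm = normalize_counts(filter_low_counts(ds.counts))
        fc = select_top_cv(fold_change_matrix(norm, ds.design), 30)
        cfg = NetworkConfig(n_trees=60, seed=5)
        edges = infer_network(fc, cfg)
        module = set(fc.index)
        full_w = module_weight_matrix(edges, module)
        reduced = loco_networks(fc, ds.design, module, cfg)
        classes = classify_edges(edge_weight_ratios(full_w, reduced))
        planted = {t.gene_id for t in ds.truths if t.klass == "ahr_module"}
        is_planted = np.array([s in planted and t in planted for s, t in classes.index])
        ch = classes["consistently_higher"].to_numpy()
        table += np.array(
            [
                [(is_planted & ch).sum(), (is_planted & ~ch).sum()],
                [(~is_planted & ch).sum(), (~is_planted & ~ch).sum()],
            ]
        )
    return table
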