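import numpy as np
import pandas as pd
import pytest

from gbmspatial.qc import NormalizedMatrix
from gbmspatial.simulate import SimulationConfig, simulate_reference, simulate_spatial


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Compact study-condition config for fast simulation-backed tests."""
    base = dict(
        n_genes=600,
        n_cells_per_type={
            "MES-like": 60, "AC-like": 60, "OPC-like": 60, "NPC-like": 60,
            "macrophage": 50, "oligodendrocyte": 40, "endothelial": 30, "neuron": 30,
        },
        grid_shape=(14, 14),
        cells_per_spot=8,
        necrosis_radius=2.0,
        marker_genes_per_type=10,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def as_normalized(values, gene_ids=None, unit_ids=None, unit_kind="cell", method="lognorm"):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    if unit_ids is None:
        unit_ids = [f"u{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(values, list(gene_ids), list(unit_ids), unit_kind, method)


@pytest.fixture(scope="session")
def small_reference():
    cfg = small_sim_config(seed=7)
    counts, truth = simulate_reference(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def small_spatial():
    cfg = small_sim_config(seed=7)
    _, ref_truth = simulate_reference(cfg)
    counts, geom, truth = simulate_spatial(cfg, ref_truth)
    return cfg, counts, geom, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
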