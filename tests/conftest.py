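import numpy as np
import pytest

import gcgrader as g
from gcgrader.simulate import MONO, POLY


@pytest.fixture(scope="session")
def small_sim():
    """A small two-sample simulation shared by read-only tests."""
    cfg = g.SimulationConfig(
        n_cells_per_sample=(300, 300),
        n_genes=120,
        n_deg=24,
        fs_fraction=(0.10, 0.85),
        seed=11,
    )
    samples, truth = g.generate_two_sample_dataset(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def study_run():
    """One full grading run at the study conditions the package targets:

    1,000 cells per sample, 200 genes, 40 planted DEGs at |log2FC| = 2,
    planted FS fractions 0.10 (monotocous) / 0.85 (polytocous), seed 42.
    Session-scoped: the run is deterministic and read-only for all tests.
    """
    sim = g.SimulationConfig(
        n_cells_per_sample=(1000, 1000),
        n_genes=200,
        n_deg=40,
        planted_log2fc=2.0,
        fs_fraction=(0.10, 0.85),
        seed=42,
    )
    model = g.GranulosaFertilityModel.from_simulation(sim)
    results = model.fit()
    planted = np.concatenate(
        [
            model.truth.cell_state[MONO].to_numpy(),
            model.truth.cell_state[POLY].to_numpy(),
        ]
    )
    return model, results, planted


@pytest.fixture(scope="session")
def toy_training_set():
    """Well-separated two-class profiles for classifier unit tests."""
    rng = np.random.default_rng(0)
    n, L = 400, 20
    X0 = rng.normal(0.30, 0.08, size=(n, L))
    X1 = rng.normal(0.70, 0.08, size=(n, L))
    X = np.clip(np.vstack([X0, X1]), 0.0, 1.0)
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return X, y
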