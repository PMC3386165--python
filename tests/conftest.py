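import numpy as np
import pytest

from perturbnet import ScreenMatrix, SimulationSpec, sample_screen


@pytest.fixture
def toy_screen() -> ScreenMatrix:
    """3 genes x (2 conditions x 2 replicates)."""
    values = np.array(
        [
            [1.0, 1.2, -0.5, -0.4],
            [0.9, 1.1, -0.6, -0.5],
            [-1.0, -1.3, 0.7, 0.8],
        ]
    )
    cols = [("vehicle", 1), ("vehicle", 2), ("serum", 1), ("serum", 2)]
    return ScreenMatrix(["tg1", "tg2", "tg3"], values, cols)


@pytest.fixture(scope="session")
def small_sim():
    """15-gene screen (5/5/5) with strong planted modules (eps=0.1)."""
    spec = SimulationSpec(n_genes=15, sizes=(5, 5, 5), noise=0.1, n_rep=8)
    screen, gold = sample_screen(spec, seed=42)
    return spec, screen, gold


@pytest.fixture(scope="session")
def block_screen() -> ScreenMatrix:
    """Two clean anti-correlated 6-gene blocks with signed mean effects.

    Block A tracks a common factor with mean +1, block B its negation with
    mean -1; residual noise is tiny, so the two blocks are unambiguous
    clusters in every replicate resample.
    """
    rng = np.random.default_rng(99)
    q = 10
    factor = rng.standard_normal(q)
    rows = []
    for _ in range(6):
        rows.append(1.0 + factor + 0.1 * rng.standard_normal(q))
    for _ in range(6):
        rows.append(-1.0 - factor + 0.1 * rng.standard_normal(q))
    genes = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    return ScreenMatrix(genes, np.array(rows), [("sim", r + 1) for r in range(q)])


@pytest.fixture(scope="session")
def medium_sim():
    """Default-size screen at moderate noise for pipeline-level tests."""
    spec = SimulationSpec(noise=0.4)
    screen, gold = sample_screen(spec, seed=7)
    return spec, screen, gold
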