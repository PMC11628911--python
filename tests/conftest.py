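import numpy as np
import pytest

from graphblup import MarkerMatrix, SimConfig, simulate_markers, simulate_phenotypes


@pytest.fixture
def tiny_markers() -> MarkerMatrix:
    """3 lines x 4 polymorphic markers with fixed dosages."""
    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 2],
            [2, 0, 1, 0],
        ],
        dtype=float,
    )
    return MarkerMatrix(["L1", "L2", "L3"], ["M1", "M2", "M3", "M4"], dosages)


@pytest.fixture(scope="session")
def sim_dataset():
    """Genotype-signal-only synthetic dataset at moderate size (shared)."""
    cfg = SimConfig(n_lines=150, n_markers=300, h2_g=0.5, seed=42)
    m = simulate_markers(cfg)
    ph, truth = simulate_phenotypes(m, cfg)
    y = ph.vector("trait1", line_order=list(m.line_ids))
    return m, ph, y, truth
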