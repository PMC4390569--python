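import numpy as np
import pandas as pd
import pytest

from ethoscan import ObservationTable, PanelSpec, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A reduced but structurally complete synthetic study."""
    spec = PanelSpec(n_lines=30, n_variants=200, n_duration_lines=20)
    return simulate_panel(spec, seed=42)


@pytest.fixture(scope="session")
def default_panel():
    """Full-scale synthetic study at the generator's default design."""
    return simulate_panel(seed=7)


@pytest.fixture()
def toy_obs_frame():
    """Two males x 30 scans in long format."""
    rows = []
    seqs = {
        ("L1", "B1", "T1", "a1", "m1"): [1] * 15 + [8] * 15,
        ("L2", "B1", "T1", "a2", "m1"): [1, 2] * 15,
    }
    for key, seq in seqs.items():
        for t, s in enumerate(seq):
            rows.append((*key, t, s))
    return pd.DataFrame(
        rows,
        columns=["line", "block", "trial", "arena", "male", "timepoint",
                 "score"],
    )


@pytest.fixture()
def toy_obs(toy_obs_frame):
    return ObservationTable.from_frame(toy_obs_frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
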