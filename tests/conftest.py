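import numpy as np
import pandas as pd
import pytest

import fmdsbr


@pytest.fixture(scope="session")
def panel():
    return fmdsbr.default_panel()


@pytest.fixture(scope="session")
def matched_panel():
    return fmdsbr.matched_mass_panel()


@pytest.fixture(scope="session")
def small_controls(panel):
    """Single-color + negative controls at n=10,000 (session-cached)."""
    truth = fmdsbr.SimulationTruth(n_events=10_000, seed=42)
    return fmdsbr.simulate_single_color_controls(truth, panel)


@pytest.fixture()
def event_table():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.lognormal(3.0, 0.5, size=(500, 4)), columns=["VL1", "VL2", "BL1", "YL1"]
    )
    return fmdsbr.EventTable(data, sample_id="toy", cocktail="none")
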