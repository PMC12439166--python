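import numpy as np
import pandas as pd
import pytest

import flavokit as fk


@pytest.fixture(scope="session")
def small_panel_spec():
    """A 4-compound x 2-enzyme panel with known truths in every category."""
    true_ic50 = pd.DataFrame(
        {
            "E1": [1e-6, 1e-7, np.nan, 2e-4],
            "E2": [5e-6, np.nan, np.nan, 1e-6],
        },
        index=["A", "B", "C", "D"],
    )
    return fk.SyntheticPanelSpec(true_ic50=true_ic50, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def study_panel():
    """Full 58x7 study-design panel with default noise plus ground truth."""
    spec, truth = fk.study_panel_spec(seed=11)
    return fk.gen_inhibition_panel(spec), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
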