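import numpy as np
import pytest
from hypothesis import settings

from tcimpact.simulate import SimConfig, simulate_panel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_panel():
    """A small panel drawn exactly from the model class with no treatment effect."""
    cfg = SimConfig(
        n_storms=1,
        n_counties=25,
        n_treated=6,
        beta_true={"intercept": 0.0},
        effect_noise_rate_sd=0.0,
        seed=42,
    )
    panel, features, truth = simulate_panel(cfg, 0)
    return panel, features, truth


@pytest.fixture(scope="session")
def short_fit(null_panel):
    """A quick 2-chain fit of the null panel, reused across tests."""
    from tcimpact.mc import NegBinMatrixCompletion

    panel, _, _ = null_panel
    est = NegBinMatrixCompletion(K=2, chains=2, draws=300, warmup=300, random_state=7)
    with np.errstate(all="ignore"):
        est.fit(panel)
    return est
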