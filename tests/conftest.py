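import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size synthetic cohort under the default study conditions."""
    from pci_traj import generate_cohort
    from pci_traj.config import SimConfig

    cfg = SimConfig(n_patients=1500, seed=42)
    cohort, panel = generate_cohort(cfg)
    return cfg, cohort, panel


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
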