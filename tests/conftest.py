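import numpy as np
import pytest

from galswitch import SyntheticConfig, default_params, generate_experiment


@pytest.fixture(scope="session")
def params():
    """Default repressor-variant parameter set."""
    return default_params("repressor")


@pytest.fixture(scope="session")
def band_150(params):
    """Saddle-node thresholds of the default set at gal = 150 nM."""
    from galswitch import bifurcation_scan

    diag = bifurcation_scan(params, 150.0, np.geomspace(2.0, 500.0, 20))
    assert diag.glu_low_star is not None and diag.glu_high_star is not None
    return diag


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced synthetic experiment (fewer events) for fast pipeline tests."""
    cfg = SyntheticConfig(seed=11, events_per_sample=1200)
    return generate_experiment(cfg)
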