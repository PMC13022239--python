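import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def farm_batch():
    """One clean farm-realistic batch (defaults, corruption disabled)."""
    from pigwater.synthetic import BatchConfig, CorruptionRates, simulate_batch

    cfg = BatchConfig(seed=42, corruption=CorruptionRates.none(), non_drinking_rate=0.0)
    return simulate_batch(cfg)


@pytest.fixture(scope="session")
def truth_batch():
    """One model-truth batch simulated from the published coefficients."""
    from pigwater.synthetic import BatchConfig, CorruptionRates, simulate_batch

    cfg = BatchConfig(mode="model-truth", duration_weeks=9, seed=1,
                      corruption=CorruptionRates.none(), non_drinking_rate=0.0)
    return simulate_batch(cfg)


@pytest.fixture(scope="session")
def truth_design(truth_batch):
    """(y, X) for the first 1512 h of the model-truth batch."""
    from pigwater.design import harmonic_design

    d = truth_batch.clean.data.iloc[:1512]
    X = harmonic_design(d.index.hour.to_numpy())
    X["temperature"] = d["temperature"].to_numpy()
    X["ammonia"] = d["ammonia"].to_numpy()
    X["fattening_day"] = d["fattening_day"].to_numpy(dtype=float)
    y = truth_batch.clean.consumption()[:1512]
    return y, X


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
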