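import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_faers():
    """10k-report generator output with a known lift, shared across tests."""
    from signalmr.synthetic import FaersSimConfig, simulate_faers

    cfg = FaersSimConfig(
        n_reports=10_000, seed=20240901, duplicate_fraction=0.08,
        association_lift={("REPATHA", "Memory impairment"): 2.0})
    return cfg, simulate_faers(cfg)


@pytest.fixture(scope="session")
def small_reports(small_faers):
    from signalmr.faers import reports_from_synthetic

    _cfg, sim = small_faers
    return reports_from_synthetic(sim)


@pytest.fixture()
def instruments():
    """Clean 20-SNP instrument set with true slope 0.5 and noise."""
    from signalmr.mr import InstrumentSet

    rng = np.random.default_rng(7)
    L = 20
    bx = rng.uniform(0.05, 0.2, L)
    se_x = np.full(L, 1e-3)
    se_y = rng.uniform(0.004, 0.01, L)
    by = 0.5 * bx + rng.normal(0, se_y)
    return InstrumentSet([f"rs{i:03d}" for i in range(L)], bx, se_x, by, se_y)
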