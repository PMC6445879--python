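import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from selmr import datasets as ds  # noqa: E402
from selmr.summary_data import HarmonizedInstrument  # noqa: E402


@pytest.fixture(scope="session")
def table1_instruments():
    """The four published instruments with exposure effects as printed (2 dp)."""
    return ds.load_instruments(rounded=True)


@pytest.fixture(scope="session")
def converted_instruments():
    """The four instruments with exposure effects re-derived from Z-scores."""
    return ds.load_instruments(rounded=False)


def random_instruments(rng: np.random.Generator, n: int) -> list[HarmonizedInstrument]:
    """Small random instrument sets for oracle-equivalence checks."""
    out = []
    for j in range(n):
        bx = rng.uniform(0.05, 0.5) * rng.choice([-1.0, 1.0])
        out.append(HarmonizedInstrument(
            rsid=f"rs{j}", effect_allele="A",
            beta_exp=bx, se_exp=rng.uniform(0.01, 0.1),
            beta_out=rng.normal(0.1 * bx, 0.05), se_out=rng.uniform(0.01, 0.1),
        ))
    return out
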