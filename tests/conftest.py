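import numpy as np
import pytest

from leadpop.correlation import AverageCorrelationSeries
from leadpop.synthetic import ArtifactInterval, SyntheticSpec, generate


@pytest.fixture(scope="session")
def short_clean_night():
    """A 600 s artifact-free synthetic recording (shared, read-only)."""
    spec = SyntheticSpec(duration_s=600, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def short_pop_night():
    """A 600 s recording with a lead pop on C3 over [400, 500)."""
    spec = SyntheticSpec(
        duration_s=600,
        seed=12,
        artifacts=[ArtifactInterval("C3", 400, 500, "pop_noise")],
    )
    return generate(spec)


def make_series(values, channel="C3", partners=("C4", "F3", "F4", "O1")):
    """Wrap a plain value array as an average-correlation series."""
    rho = np.asarray(values, dtype=float)
    return AverageCorrelationSeries(
        channel=channel,
        avg_rho=rho,
        active_partners=frozenset(partners),
        n_pairs=np.where(np.isfinite(rho), len(partners), 0),
    )
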