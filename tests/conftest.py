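import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import upievol as uv

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def linked_small():
    """Fast linked configuration: high mutation rate, loose tolerance."""
    return uv.RunConfig(
        n=8,
        mu=1e-3,
        scenario=uv.build_linked(),
        fitness=uv.FitnessSpec(0.2, "concave"),
        eq_tol=1e-10,
        trace_every=100,
    )


@pytest.fixture
def random_gametes():
    """A normalized but otherwise arbitrary three-allele gamete distribution."""
    rng = np.random.default_rng(7)
    n = 8
    props = {g: rng.random(n // 2 + 1) for g in ("U1", "B1", "B2")}
    tot = sum(v.sum() for v in props.values())
    return uv.GameteDistribution(n, {g: v / tot for g, v in props.items()})
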