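import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import profreg as pr

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """Well-separated four-cluster truth used across modules."""
    return pr.icare_like_truth(modal_prob_reference=0.97, modal_prob=0.92)


@pytest.fixture(scope="session")
def small_fit(small_truth):
    """A modest end-to-end fit (N=500) shared by post-processing,
    prediction and evaluation tests."""
    data, labels = pr.generate_population(small_truth, 500, seed=42)
    chain = pr.run_chain(
        data,
        pr.PriorSpec(),
        pr.SamplerControls(n_sweeps=1200, n_burnin=600, thin=5, seed=43),
    )
    return {"truth": small_truth, "data": data, "labels": labels, "chain": chain}
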