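import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across tests."""
    from moodcast.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_patients=12, seq_length_mean=80, seq_length_sd=10, valence_report_rate=0.5, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_hmm_params():
    from moodcast.hmm import HHMMParams

    return HHMMParams(
        start_probs=np.array([0.6, 0.4]),
        transition=np.array([[0.7, 0.3], [0.2, 0.8]]),
        gauss_means=np.array([[0.0, 1.0], [2.0, -1.0]]),
        gauss_sds=np.array([[1.0, 0.5], [0.7, 1.2]]),
        bern_p=np.array([0.2, 0.9]),
    )
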