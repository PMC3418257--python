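import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qrepbmd.adjustment import fit_all, zscores
from qrepbmd.monte_carlo import CorrelationModel
from qrepbmd.synthetic_cohorts import (
    AlleleModel,
    StudySpec,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> StudySpec:
    """A compact four-site cohort for fast end-to-end checks."""
    return StudySpec(
        name="toy", n_subjects=600, age_range=(45, 75),
        site_panel=("FN", "LS", "HIP", "TB"),
    )


@pytest.fixture(scope="session")
def enriched_allele() -> AlleleModel:
    """Carrier frequency raised so small cohorts contain carriers."""
    return AlleleModel(carrier_frequency=0.03, effect=-0.7)


@pytest.fixture(scope="session")
def toy_ztable(small_spec, enriched_allele):
    """Z-score table for one simulated cohort with carriers."""
    records = simulate_cohort(small_spec, enriched_allele, seed=7)
    models = fit_all(records)
    return zscores(records, models)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
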