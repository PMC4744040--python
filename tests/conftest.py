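import logging

import pytest

from mrlipids import pipeline
from mrlipids.simulate import SimulationConfig, generate_cohort

# carrier warnings are expected for the rare ADH1B variant at test-size n
logging.getLogger("mrlipids.simulate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design cohort at a size where pipeline tests stay fast."""
    cohort, truth = generate_cohort(SimulationConfig(n_individuals=4000, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def scored_cohort(small_cohort):
    """Derived + instrument-scored version of the small cohort."""
    cohort, _ = small_cohort
    derived = pipeline.prepare_cohort(cohort)
    scored, report, score, survivors = pipeline.select_instruments(derived)
    return scored
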