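import numpy as np
import pytest

from tdconnect import offers_behavior as ob
from tdconnect import pipeline
from tdconnect.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def grid():
    return ob.load_offer_grid()


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort with a strong planted connectivity effect."""
    return generate_cohort(CohortConfig(n_subjects=6, seed=101, effect_size=0.4))


@pytest.fixture(scope="session")
def small_cohort_behaviors(small_cohort):
    return pipeline.fit_cohort_behavior(small_cohort)


@pytest.fixture(scope="session")
def small_cohort_posteriors(small_cohort, small_cohort_behaviors):
    """Full-model posteriors for run 1 of the six-subject cohort."""
    return pipeline.invert_cohort(
        small_cohort, behaviors=small_cohort_behaviors, runs=(1,)
    )


def simulate_choices(trials, k, b, rng):
    """Realize accept/reject choices from the softmax model in place."""
    for t in trials:
        p = ob.p_accept(ob.discounted_value(t.offer, k), b)
        t.choice = "accept" if rng.random() < p else "reject"
        t.rt = 1.2
    return trials
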