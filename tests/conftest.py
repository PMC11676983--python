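import pytest

from tmsdr.conditions import DEFAULT_INITIAL, REFERENCE_CONDITIONS
from tmsdr.observation_model import (
    CalibrationSet,
    aggregate_replicates,
    normalize_to_substitution,
)
from tmsdr.synthetic_data import SyntheticProtocol, generate


@pytest.fixture(scope="session")
def reference_conditions():
    """The four labelled constructs with their fitted rate constants."""
    return REFERENCE_CONDITIONS


@pytest.fixture(scope="session")
def initial():
    """Equal 10 nM invader and gate, no products."""
    return DEFAULT_INITIAL


@pytest.fixture(scope="session")
def aggregated_course_factory():
    """Generate a synthetic dataset and reduce it to a mean substitution course."""

    def factory(system, seed=1, noise_sd=0.02, **protocol_kwargs):
        protocol = SyntheticProtocol(seed=seed, noise_sd=noise_sd, **protocol_kwargs)
        dataset = generate(system, DEFAULT_INITIAL, protocol)
        calib = CalibrationSet(
            dataset.baseline, dataset.positive_control, DEFAULT_INITIAL.x1
        )
        courses = [
            normalize_to_substitution(trace, calib) for trace in dataset.reaction
        ]
        return aggregate_replicates(courses)

    return factory
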