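import numpy as np
import pytest

from asgo.instrument import (
    ASGO_VARIABLES,
    AsgoAssessment,
    load_default_instrument,
)


@pytest.fixture(scope="session")
def instrument():
    return load_default_instrument()


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient synthetic cohort shared across read-only tests."""
    from asgo.cohort import CohortConfig, generate_cohort

    config = CohortConfig(n_patients=120, seed=7)
    return generate_cohort(config), config


def assessment_at_positions(instrument, positions, timepoint="admission"):
    """Single-select assessment with each variable at a given modality
    position (0-based index into its printed modality list)."""
    selections = {}
    for i, name in enumerate(ASGO_VARIABLES):
        var = instrument.variable(name)
        pos = positions[i] if not np.isscalar(positions) else positions
        pos = int(np.clip(pos, 0, len(var.modalities) - 1))
        selections[name] = frozenset({var.modalities[pos].level})
    return AsgoAssessment(selections=selections, timepoint=timepoint)
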