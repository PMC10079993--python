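import numpy as np
import pytest

from plinet.synthetic import (CohortSpec, CouplingRule, GroupProfile,
                              generate_cohort, load_cohort)


def tiny_cohort_spec(seed: int = 11) -> CohortSpec:
    """Three small groups with distinct theta coupling, few stimuli: fast."""
    groups = [
        GroupProfile("cpp", [CouplingRule(("FP1", "P3"), "theta", 1.0, 10.0)]),
        GroupProfile("dd", [CouplingRule(("FP1", "P3"), "theta", 1.0, 0.5)]),
        GroupProfile("hc", [CouplingRule(("CP5", "O2"), "theta", 1.0, 6.0)]),
    ]
    return CohortSpec(groups=groups, n_subjects_per_group=2, seed=seed,
                      n_target=10, n_standard=30)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """On-disk 3x2-subject cohort shared across tests."""
    path = tmp_path_factory.mktemp("cohort") / "tiny"
    generate_cohort(tiny_cohort_spec(), path)
    return load_cohort(path)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
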