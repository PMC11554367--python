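import numpy as np
import pytest

import refrange as rr


@pytest.fixture(scope="session")
def default_spec() -> rr.CohortSpec:
    return rr.CohortSpec(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """The default synthetic cohort (n=20,000, 25% contamination)."""
    return rr.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    """Retained records and audit after the default exclusion criteria."""
    deduped = rr.dedupe_subjects(default_cohort)
    return rr.apply_exclusions(deduped)


@pytest.fixture(scope="session")
def fast_config() -> rr.RIConfig:
    """Pipeline config with a small bootstrap for tests that ignore CIs."""
    return rr.RIConfig(n_boot=25)
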