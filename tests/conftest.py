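import pytest

from pedcan.config import RuleConfig
from pedcan.simulate import CohortSpec, generate_cohort, load_cohort_evidence


@pytest.fixture(scope="session")
def cfg():
    return RuleConfig()


@pytest.fixture(scope="session")
def noiseless_cohort(tmp_path_factory):
    """One full noiseless synthetic cohort (catalog coverage), generated once."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(CohortSpec(seed=11), out)
    return out, manifest


@pytest.fixture(scope="session")
def noiseless_evidence(noiseless_cohort):
    out, manifest = noiseless_cohort
    return load_cohort_evidence(out), manifest
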