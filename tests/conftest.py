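"""Shared fixtures: one synthetic truth bundle reused across the suite."""

import pytest

from finishkit import synthetic as syn

SEED = 1


@pytest.fixture(scope="session")
def truth():
    return syn.simulate_truth(seed=SEED)


@pytest.fixture(scope="session")
def cohort_vcf(truth, tmp_path_factory):
    path = tmp_path_factory.mktemp("vcf") / "cohort.vcf"
    path.write_text(syn.simulate_cohort(truth))
    return str(path)
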