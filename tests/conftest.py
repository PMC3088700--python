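import pytest
from hypothesis import settings

from mutbench.cohort import load_table1
from mutbench.pyro import PyroAssay

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def egfr_del_assay():
    """Synthetic EGFR exon 19 15-bp deletion assay (bundled config values)."""
    return PyroAssay(
        wt_template="ATCAAGGAATTAAGAGAAGCAACATCTCCGAAAGCCAAC",
        mut_template="ATCAAGAACATCTCCGAAAGCCAAC",
        noise_sd=0.05,
        name="egfr_ex19_del",
    )
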