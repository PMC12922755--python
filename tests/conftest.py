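import numpy as np
import pytest

from aneucall.genome_model import GenomeBuild, arm_bin_ranges, arm_defs, make_bins


@pytest.fixture(scope="session")
def hg19():
    return GenomeBuild.hg19()


@pytest.fixture(scope="session")
def hg19_bins(hg19):
    return make_bins(hg19)


@pytest.fixture(scope="session")
def hg19_arm_ranges(hg19, hg19_bins):
    return arm_bin_ranges(hg19_bins, arm_defs(hg19, hg19_bins))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_cohort():
    """Moderate seeded cohort shared by recovery tests."""
    from aneucall.synthetic_cohort import CohortConfig, simulate_cohort

    cfg = CohortConfig(
        seed=7,
        n_per_grade={"NORMAL": 5, "LG_PANIN": 40, "HG_PANIN": 40,
                     "LG_IPMN": 40, "HG_IPMN": 40, "MCN": 3, "SCA": 3,
                     "PDAC": 80},
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_arm_calls(demo_cohort):
    from aneucall.cna_calls import call_arms

    return call_arms(demo_cohort.matrix, demo_cohort.build)
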