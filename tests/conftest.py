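import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from agmap.mapping import LinkageMapper
from agmap.qc import MarkerQC
from agmap.simulate import SimCrossConfig, default_map_truth, simulate_cp_cross

settings.register_profile(
    "agmap",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("agmap")


@pytest.fixture(scope="session")
def study_cross():
    """A CP cross at the study's design conditions.

    Seven chromosomes, 100 markers each with the 45/27/28 hk/lm/nn
    pattern mix, 119 progeny, 1% genotyping error, 15% missing calls.
    """
    truth = default_map_truth(seed=1)
    gm, sim_truth = simulate_cp_cross(truth, SimCrossConfig(seed=2))
    return truth, gm, sim_truth


@pytest.fixture(scope="session")
def study_mapper(study_cross):
    """QC + fitted LinkageMapper on the study-condition cross."""
    _, gm, _ = study_cross
    qc = MarkerQC().fit(gm)
    mapper = LinkageMapper().fit(gm, qc_table=qc.table_)
    return qc, mapper


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
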