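import numpy as np
import pytest

from qtlfine.intervals import GenomicInterval
from qtlfine.variants import StrainPanel
from qtlfine.pipeline import StudyConfig, build_study, run_study

STUDY_SEED = 1  # fixed seed of the default synthetic study


@pytest.fixture(scope="session")
def panel() -> StrainPanel:
    return StrainPanel("C57BL6J", ("NZO",), "DBA")


@pytest.fixture(scope="session")
def study():
    """The default synthetic study, generated once per session."""
    return build_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_result(study):
    return run_study(study, seed=STUDY_SEED, n_perm=200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def region(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)
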