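import numpy as np
import pytest

from igpipe.pipeline import StudyOptions, prepare_study
from igpipe.population import Pedigree
from igpipe.simulate import SimulationConfig, simulate


def make_random_pedigree(n: int, n_founders: int, seed: int) -> Pedigree:
    """Random valid pedigree: founders first, later animals draw a sire and
    dam among earlier animals of the right sex."""
    rng = np.random.default_rng(seed)
    ids = np.arange(1, n + 1)
    sex = np.where(np.arange(n) % 2 == 0, "M", "F")
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    year = np.zeros(n, dtype=np.int64) + 2000
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i] == "M")
        females = np.flatnonzero(sex[:i] == "F")
        sire[i] = ids[rng.choice(males)]
        dam[i] = ids[rng.choice(females)]
        year[i] = 2000 + 1 + (i - n_founders) * 5 // max(n - n_founders, 1)
    return Pedigree(ids, sire, dam, year, sex)


SMALL_CONFIG = SimulationConfig(
    n_founders=300, offspring_per_dam=6, n_generations=4, n_markers=300, seed=11
)


@pytest.fixture(scope="session")
def small_data():
    """A ~1,600-animal simulated population reused across module tests."""
    return simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_study(small_data):
    """Benchmark + reduced solves on the small population (cutoff: last
    generation year)."""
    cfg = small_data.config
    return prepare_study(
        small_data.pedigree,
        small_data.genotypes,
        small_data.phenotypes,
        small_data.variance_components,
        cfg.start_year + cfg.n_generations - 1,
        StudyOptions(),
    )
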