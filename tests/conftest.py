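import pytest

from pansubspec.config import CohortConfig
from pansubspec.pipeline import run_pipeline
from pansubspec.simulate import generate_cohort, sample_family_universe

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """The default three-subspecies cohort (3 x 10 genomes, ~200 CDS each)."""
    cfg = CohortConfig(seed=DEFAULT_SEED)
    universe = sample_family_universe(cfg)
    records, truth = generate_cohort(universe, cfg)
    return cfg, universe, records, truth


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    """Full pipeline result on the default cohort (shared: it is expensive)."""
    cfg, _, records, truth = default_cohort
    return run_pipeline(records, truth.thresholds, seed=cfg.seed,
                        type_strains=truth.type_strains)


@pytest.fixture()
def small_config():
    """A miniature cohort for cheap structural tests."""
    return CohortConfig(n_genomes_per_subspecies=(4, 4, 4), n_core=30,
                        n_marker=3, n_shell=10, n_cloud=15, n_duplicates=1,
                        n_qc_violators=2, n_mislabelled=1, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_genomes_per_subspecies=(4, 4, 4), n_core=30,
                       n_marker=3, n_shell=10, n_cloud=15, n_duplicates=1,
                       n_qc_violators=2, n_mislabelled=1, seed=11)
    universe = sample_family_universe(cfg)
    records, truth = generate_cohort(universe, cfg)
    return cfg, universe, records, truth
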