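import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from phenocomm import (
    EffectConfig,
    generate_phenotype_matrix,
    generate_reference_database,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_ref_db():
    """6 species x 2 strains: enough structure for every stage, fast to align."""
    return generate_reference_database(n_species=6, strains_per_species=2, seed=11)


@pytest.fixture(scope="session")
def small_bpm(small_ref_db):
    return generate_phenotype_matrix(small_ref_db, seed=12)


@pytest.fixture(scope="session")
def small_experiment(small_ref_db):
    cfg = EffectConfig(seed=13, depth=20_000, multiplier_low=10.0, multiplier_high=10.0,
                       fraction_affected=0.2)
    return simulate_experiment(small_ref_db, cfg)


@pytest.fixture(scope="session")
def study_scale_experiment():
    """The full study design: 10 species x 3 strains, 1 control + 9 SCFA
    conditions x 4 replicates, depth 100,000, 10-fold fitness reductions
    planted on 10% of strains per condition."""
    ref_db = generate_reference_database(n_species=10, strains_per_species=3, seed=101)
    bpm = generate_phenotype_matrix(ref_db, seed=102)
    cfg = EffectConfig(seed=103, depth=100_000, replicates=4,
                       fraction_affected=0.1, multiplier_low=0.1, multiplier_high=0.1)
    counts, truth = simulate_experiment(ref_db, cfg)
    return ref_db, bpm, cfg, counts, truth
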