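import numpy as np
import pytest

from nccm.synthetic_cohort import (
    AgeModel,
    CohortSpec,
    PlantedDriver,
    SimulationConfig,
    simulate_study,
)


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A compact two-cohort study: 2 x 300 kb chromosomes, 14 genes,
    20 kb flanks so target regions have interesting structure."""
    base = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length_bp=300_000,
        n_genes=14,
        gene_span_bp_range=(6_000, 15_000),
        flank_bp=20_000,
        indel_fraction=0.05,
        cohorts=(
            CohortSpec(
                name="MB", n_samples=12, mutations_mean=120.0,
                subgroup_proportions={"SHH": 0.3, "Group3": 0.3,
                                      "Group4": 0.3, "NA": 0.1},
                age_model=AgeModel(adult_fraction=0.2,
                                   adult_fraction_by_subgroup={"SHH": 0.6}),
                planted_drivers=(PlantedDriver("G00002", 8.0),),
            ),
            CohortSpec(name="PA", n_samples=8, mutations_mean=30.0),
        ),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def study():
    return simulate_study(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(20230807)
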