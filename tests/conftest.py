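import numpy as np
import pytest

from haploscan.pipeline import fit_null_model
from haploscan.simulate import PlantedEffect, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def sim_cohort():
    """A small family cohort with one planted causal haplotype."""
    cfg = SimConfig(
        n_individuals=300,
        n_snps=400,
        map_length_cm=2.0,
        prevalence=0.139,
        h2=0.3,
        planted=(PlantedEffect(locus_cm=1.0, target_freq=0.1, beta_liability=0.45),),
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no genetic signal at all (h² = 0, nothing planted)."""
    cfg = SimConfig(
        n_individuals=300, n_snps=300, map_length_cm=1.5, h2=0.0, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_scan(sim_cohort):
    """Null-model REML fit and scan projector for the planted cohort."""
    panel, phen, gmap, truth = sim_cohort
    scan, vc, X = fit_null_model(
        panel, phen, ("sex", "age"), two_grm=True, grm_cutoff=0.05, maf_min=0.01
    )
    return scan, vc, X


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
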