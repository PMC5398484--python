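import numpy as np
import pytest

from gxcset import (
    CovariateMatrix,
    SimulationConfig,
    StudyDesign,
    compute_pcs,
    simulate_mosaic_cohort,
    simulate_phenotypes,
    standardize_region,
)


@pytest.fixture(scope="session")
def background_cohort():
    """Genome-wide-style cohort (N=500) used as the structure source."""
    return simulate_mosaic_cohort(
        500, n_variants=300, region_length_bp=300_000, recomb_rate=1e-5, seed=11
    )


@pytest.fixture(scope="session")
def region_500(background_cohort):
    """A 30-kb testing region for the N=500 cohort."""
    dm = simulate_mosaic_cohort(500, n_variants=60, region_length_bp=30_000, seed=12)
    return standardize_region(dm, maf_min=0.02)


@pytest.fixture(scope="session")
def covariates_500(background_cohort):
    pcs = compute_pcs(background_cohort, n_components=10)
    return CovariateMatrix.build(500, pcs=pcs).values


@pytest.fixture(scope="session")
def persistent_design(region_500, background_cohort, covariates_500):
    bundle = simulate_phenotypes(
        SimulationConfig(architecture="persistent", seed=21), region_500, background_cohort
    )
    return StudyDesign(layout="complete", Y=bundle.Y, F=covariates_500)


def make_region(n=60, s=20, seed=0):
    """Small standardized region (independent Gaussian variants)."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, s))
    G = (G - G.mean(axis=0)) / G.std(axis=0)
    from gxcset import RegionGenotypes

    return RegionGenotypes(G)


@pytest.fixture(scope="session")
def region_factory():
    return make_region
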