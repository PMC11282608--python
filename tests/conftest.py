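import numpy as np
import pandas as pd
import pytest

from hetscan import default_study_config, simulate_population
from hetscan.genotype_io import GenotypeMatrix
from hetscan.diversity_stats import snp_her_incidence, tajimas_d
from hetscan.parameter_sweep import (
    ADDITIONAL_SCENARIOS,
    run_grid,
    run_scenarios,
)

REFERENCE_SEED = 1


def make_gm(geno, pos, chrom="1", samples=None):
    """Build a GenotypeMatrix from an (individuals x sites) code array.

    ``geno`` uses the package coding (-1 missing, 0 hom-ref, 1 het,
    2 hom-alt); ``pos``/``chrom`` may be per-site arrays.
    """
    geno = np.asarray(geno, dtype=np.int8)
    if geno.ndim == 1:
        geno = geno[None, :]
    n_ind, n_sites = geno.shape
    pos = np.asarray(pos, dtype=np.int64)
    chroms = np.repeat(chrom, n_sites) if isinstance(chrom, str) else np.asarray(chrom)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": pos,
         "ref": ["A"] * n_sites, "alt": ["C"] * n_sites}
    )
    if samples is None:
        samples = [f"s{i}" for i in range(n_ind)]
    return GenotypeMatrix(samples=samples, sites=sites, calls=geno)


def random_gm(rng, n_ind=6, n_sites=10, missing_rate=0.1, chrom="1"):
    geno = rng.choice([0, 1, 2], size=(n_ind, n_sites)).astype(np.int8)
    miss = rng.random((n_ind, n_sites)) < missing_rate
    geno[miss] = -1
    pos = np.cumsum(rng.integers(1, 1000, size=n_sites)).astype(np.int64)
    return make_gm(geno, pos, chrom=chrom)


@pytest.fixture(scope="session")
def ref_population():
    """The reference simulated population: 200 individuals, two 5-Mb
    chromosomes, five planted islands (het_prob 0.95, carrier 0.5)."""
    gm, truth = simulate_population(default_study_config(seed=REFERENCE_SEED))
    return gm, truth


@pytest.fixture(scope="session")
def ref_gm(ref_population):
    return ref_population[0]


@pytest.fixture(scope="session")
def ref_truth(ref_population):
    return ref_population[1]


@pytest.fixture(scope="session")
def scenarios9_results(ref_gm):
    return run_scenarios(ref_gm, ADDITIONAL_SCENARIOS, keep_hers=True)


@pytest.fixture(scope="session")
def scenarios9_tracks(ref_gm, scenarios9_results):
    return {r.name: snp_her_incidence(r.hers, ref_gm) for r in scenarios9_results}


@pytest.fixture(scope="session")
def full_grid_results(ref_gm):
    return run_grid(ref_gm, keep_hers=False)


@pytest.fixture(scope="session")
def ref_tajima(ref_gm):
    return tajimas_d(ref_gm, window_bp=10_000)
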