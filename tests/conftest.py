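import numpy as np
import pytest

from dmrkit.simulate import SimConfig, build_reference, simulate_methylomes
from dmrkit.pipeline import run_pipeline
from dmrkit.types import CpGMethylomeMatrix

DEFAULT_SEED = 11


def small_config() -> SimConfig:
    """A fast single-chromosome variant of the default study conditions."""
    return SimConfig(n_chroms=1, chrom_length=2_000_000, n_genes=40,
                     n_dedm=6, n_cliffs=2, n_dmv_cliffs=1,
                     n_promoter_dmr_only=4, n_intergenic_dmr=8, n_dmv=2,
                     n_shared_lmr=10, n_dlmr_per_group=3, n_extra_de=5)


@pytest.fixture(scope="session")
def small_ref():
    return build_reference(small_config(), seed=5)


@pytest.fixture(scope="session")
def small_meth(small_ref):
    return simulate_methylomes(small_ref, seed=5)


@pytest.fixture(scope="session")
def default_result():
    """The default study-scale simulation run end-to-end once per session."""
    return run_pipeline(seed=DEFAULT_SEED)


def flat_matrix(n_sites=50, spacing=100, frac=0.5, coverage=20,
                n_per_group=2, chrom="chr1") -> CpGMethylomeMatrix:
    """Noise-free matrix with every sample at an exact methylation fraction."""
    pos = np.arange(n_sites) * spacing + 1000
    samples = [f"A_{i+1}" for i in range(n_per_group)] + \
              [f"B_{i+1}" for i in range(n_per_group)]
    groups = {s: s.split("_")[0] for s in samples}
    total = np.full((n_sites, len(samples)), coverage, dtype=int)
    meth = np.round(total * frac).astype(int)
    return CpGMethylomeMatrix(np.full(n_sites, chrom, dtype=object), pos,
                              samples, groups, meth, total)
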