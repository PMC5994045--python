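import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from declinomics import synthio
from declinomics.variants import VariantTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(genotypes, positions=None, contigs=None, samples=None) -> VariantTable:
    """Small helper: build a VariantTable from a genotype matrix."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n = gt.shape[0]
    if positions is None:
        positions = np.arange(1, n + 1) * 1_000
    if contigs is None:
        contigs = ["chr1"] * n
    return VariantTable(
        contigs=np.array(contigs, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["C"] * n, dtype=object),
        genotypes=gt,
        samples=samples or [f"s{i}" for i in range(gt.shape[1])],
    )


@pytest.fixture
def structured_small():
    """2 demes x 20 samples x 500 sites Balding-Nichols draw, F = 0.15."""
    spec = synthio.StructuredGenotypeSpec(
        n_demes=2, n_per_deme=20, n_sites=500, fst_target=0.15, seed=11
    )
    return synthio.gen_structured_genotypes(spec)
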