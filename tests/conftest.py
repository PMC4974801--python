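import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from clonalpop.align_io import Alignment
from clonalpop.synthetic_data import generate_toy_genome, plant_snps


@pytest.fixture(scope="session")
def toy_genome():
    """A 30-gene toy genome with interleaved intergenic spacers."""
    reference, annotation = generate_toy_genome(
        n_cds=30, cds_len=300, igr_len=100, seed=11
    )
    return reference, annotation


@pytest.fixture(scope="session")
def planted(toy_genome):
    reference, annotation = toy_genome
    records = plant_snps(
        reference, annotation, {"sSNP": 20, "nsSNP": 30, "iSNP": 10}, seed=5
    )
    return reference, annotation, records


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_alignment(rng, n, L, p_var=0.1):
    """Random alignment helper used by the brute-force oracle tests."""
    base = rng.choice(list("ACGT"), size=L)
    mat = np.tile(base, (n, 1))
    for c in range(L):
        if rng.random() < p_var:
            alt = rng.choice([b for b in "ACGT" if b != base[c]])
            carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
            mat[carriers, c] = alt
    return Alignment(
        ids=tuple(f"s{i}" for i in range(n)),
        seqs=tuple("".join(row) for row in mat),
    )
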