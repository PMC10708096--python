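import numpy as np
import pytest

from snpdiv.io_formats import MISSING, GenotypeMatrix, SnpLocus
from snpdiv.synthetic_data import SimulationConfig, reference_fixture, simulate


@pytest.fixture(scope="session")
def fixture_dataset():
    """The packaged deterministic 84 x 150 dataset (shared across tests)."""
    return reference_fixture()


@pytest.fixture(scope="session")
def two_pop_dataset():
    """84 x 91 pure two-population simulation at F = 0.3, no defects."""
    cfg = SimulationConfig(
        k_true=2, drift_f=0.3, n_accessions=84, n_loci=91, admixture_alpha=0.0, seed=42
    )
    return simulate(cfg)


def random_matrix(rng: np.random.Generator, n: int, l: int, missing_rate: float = 0.1):
    """Unstructured random genotype matrix for property tests."""
    dosage = rng.integers(0, 3, size=(n, l)).astype(np.int8)
    mask = rng.random((n, l)) < missing_rate
    dosage[mask] = MISSING
    return GenotypeMatrix(
        accession_ids=[f"a{i}" for i in range(n)],
        locus_ids=[f"L{j}" for j in range(l)],
        dosage=dosage,
    )


def make_locus(i: int, chrom: str, pos: int, maf: float | None = None) -> SnpLocus:
    return SnpLocus(
        locus_id=f"m{i:04d}",
        chromosome=chrom,
        position=pos,
        ref_allele="A",
        alt_allele="G",
        maf=maf,
    )
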