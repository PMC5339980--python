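import numpy as np
import pytest

from seqselect import simdata
from seqselect.containers import GenotypeMatrix, Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog():
    """Two chromosomes x 200 variants with assigned frequencies."""
    return simdata.build_catalog(
        n_chromosomes=2, variants_per_chromosome=200,
        chromosome_length_bp=1_000_000, seed=7,
    )


@pytest.fixture
def trio_pedigree():
    """Founder pair plus two offspring (one with a single known parent)."""
    return Pedigree.from_records(
        [("S", "0", "0"), ("D", "0", "0"), ("O1", "S", "D"), ("O2", "S", "0")]
    )


def make_genotypes(dosages, animal_ids=None, variant_ids=None, **kw):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if animal_ids is None:
        animal_ids = np.array([f"a{i}" for i in range(n)], dtype=object)
    if variant_ids is None:
        variant_ids = np.array([f"v{j}" for j in range(m)], dtype=object)
    return GenotypeMatrix(animal_ids, variant_ids, dosages, **kw)


@pytest.fixture
def make_gm():
    return make_genotypes


@pytest.fixture(scope="session")
def default_runs():
    """Three replicate runs of the full pipeline at the default desk scale.

    Shared across the end-to-end tests; each run takes a few minutes, so
    they are computed once per session.
    """
    from seqselect.config import ExperimentConfig
    from seqselect.pipeline import run_experiment

    return [run_experiment(ExperimentConfig(), seed=s) for s in (1, 2, 3)]
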