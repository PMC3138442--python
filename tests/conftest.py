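import numpy as np
import pytest

import segdistort as sd
from segdistort.genotypes import Cohort, GenotypeMatrix, Individual, MarkerDef, Sex

TOKEN_CODE = {"AA": 0, "AB": 1, "BB": 2, "NA": 3}


def make_matrix(token_rows, cohort=Cohort.F2_ADULT_MALE, markers=None, chromosomes=None):
    """Small genotype matrix from rows of AA/AB/BB/NA tokens."""
    n_mark = len(token_rows[0])
    if markers is None:
        markers = [f"M{j + 1}" for j in range(n_mark)]
    if chromosomes is None:
        chromosomes = [None] * n_mark
    defs = [MarkerDef(m, chromosome=c) for m, c in zip(markers, chromosomes)]
    individuals = [
        Individual(f"I{i + 1}", Cohort(cohort), family="F1", sex=Sex.UNKNOWN)
        for i in range(len(token_rows))
    ]
    calls = np.array([[TOKEN_CODE[t] for t in row] for row in token_rows], dtype=np.int8)
    return GenotypeMatrix(individuals, defs, calls)


@pytest.fixture(scope="session")
def null_cross():
    """One simulated default cross (no selection): nauplii, adults, NR-BC."""
    cfg = sd.CrossConfig(seed=11)
    rng = np.random.default_rng(11)
    nauplii, adults = sd.simulate_f2_cohorts(cfg, rng=rng)
    nrbc = sd.simulate_nrbc(cfg, rng=rng)
    return cfg, nauplii, adults, nrbc


@pytest.fixture(scope="session")
def big_null_f2():
    """A large no-selection, no-error F2 cohort for frequency checks."""
    cfg = sd.CrossConfig(
        n_nauplii=10_000,
        n_adult_males=10,
        error_model=sd.ErrorModel(0.0, 0.0),
        seed=23,
    )
    nauplii, _ = sd.simulate_f2_cohorts(cfg, rng=np.random.default_rng(23))
    return nauplii
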