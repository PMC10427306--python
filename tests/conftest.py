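import numpy as np
import pytest

from campkin import (
    GeneratorConfig,
    IndividualRecord,
    Pedigree,
    generate_population,
    kinship_matrix,
    named_pedigree_fixtures,
    relatedness_matrix,
    worked_example_fixture,
)
from campkin.pedigree import FEMALE, MALE


def random_pedigree(seed: int, n: int = 30) -> Pedigree:
    """Random acyclic pedigree: each individual may take parents among the
    previously created males/females, so ancestry (and inbreeding) arises
    naturally.  Used as the substrate for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    records = []
    males: list[str] = []
    females: list[str] = []
    for k in range(n):
        sex = MALE if rng.random() < 0.5 else FEMALE
        father = mother = None
        if males and females and rng.random() < 0.7:
            father = males[rng.integers(len(males))]
            mother = females[rng.integers(len(females))]
        iid = f"P{k:03d}"
        records.append(
            IndividualRecord(id=iid, father_id=father, mother_id=mother,
                             sex=sex)
        )
        (males if sex == MALE else females).append(iid)
    return Pedigree(records)


@pytest.fixture(scope="session")
def catalogue():
    return named_pedigree_fixtures()


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def default_population():
    return generate_population(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_relatedness(default_population):
    ped, _ = default_population
    return relatedness_matrix(kinship_matrix(ped))
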