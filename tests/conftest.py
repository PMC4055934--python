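import logging

import pytest

from divergekit.records import (
    FIDTrial,
    GenotypeTable,
    PredationCounts,
    QuadrateObservation,
)


@pytest.fixture(autouse=True)
def quiet_logs():
    """Index operations log skip warnings; keep test output readable."""
    logger = logging.getLogger("divergekit")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture
def toy_genepop(tmp_path):
    """2 pops x 2 individuals x 2 loci, 3-digit coding, one missing call."""
    text = (
        "toy file\n"
        "locA\n"
        "locB\n"
        "pop\n"
        "popA , 001001 002003\n"
        "popA , 001002 000000\n"
        "pop\n"
        "popB , 002002 003003\n"
        "popB , 001001 002003\n"
    )
    path = tmp_path / "toy.gen"
    path.write_text(text)
    return path


@pytest.fixture
def fixed_pair_table():
    """Two populations fixed for different alleles at one locus."""
    return GenotypeTable(
        populations=["A", "B"],
        loci=["L1"],
        individual_pops=["A"] * 4 + ["B"] * 4,
        calls=[[(1, 1)]] * 4 + [[(2, 2)]] * 4,
    )


@pytest.fixture
def quadrate_obs():
    def make(quadrate_id, idx, males, females, area=0.25):
        return QuadrateObservation(
            population="P", quadrate_id=quadrate_id, observation_index=idx,
            n_males=males, n_females=females, n_juveniles=0,
            exposed_area_m2=area)

    return make


@pytest.fixture
def fid_trial():
    def make(d_start, d_flee, sex="M"):
        return FIDTrial(population="P", sex=sex, d_start_paces=d_start,
                        d_flee_paces=d_flee)

    return make
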