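import logging

import pandas as pd
import pytest

from famrisk import SimConfig, build_pedigree, generate_population

logging.disable(logging.WARNING)


def four_gen_family() -> pd.DataFrame:
    """A hand-built four-generation family with every relationship class
    the classifier must distinguish (grandparents on both sides, aunt and
    uncle, first cousin, maternal half-sibling, nephew, great-grandparents,
    and unrelated in-laws)."""
    rows = [
        # person_id, sex, birth_year, mother_id, father_id
        (1, "M", 1880, None, None),   # paternal great-grandfather
        (2, "F", 1882, None, None),   # paternal great-grandmother
        (3, "M", 1905, 2, 1),         # paternal grandfather
        (4, "F", 1907, None, None),   # paternal grandmother
        (5, "M", 1906, None, None),   # maternal grandfather
        (6, "F", 1908, None, None),   # maternal grandmother
        (7, "M", 1930, 4, 3),         # father
        (8, "F", 1932, 6, 5),         # mother
        (9, "M", 1933, 4, 3),         # paternal uncle
        (10, "F", 1934, 6, 5),        # maternal aunt
        (11, "M", 1933, None, None),  # aunt's husband (unrelated)
        (12, "F", 1958, 10, 11),      # maternal first cousin
        (13, "M", 1955, 8, 7),        # proband
        (14, "F", 1957, 8, 7),        # full sister
        (15, "M", 1980, 16, 13),      # proband's child
        (16, "F", 1956, None, None),  # proband's wife (unrelated)
        (17, "M", 1960, 8, 18),       # maternal half-brother
        (18, "M", 1930, None, None),  # half-brother's father (unrelated)
        (19, "F", 1982, 14, 20),      # niece (sister's daughter)
        (20, "M", 1956, None, None),  # sister's husband (unrelated)
        (21, "M", 2005, None, 15),    # grandchild (child's son, mother unknown)
    ]
    return pd.DataFrame(
        rows, columns=["person_id", "sex", "birth_year", "mother_id", "father_id"]
    ).assign(utah_born=True)


PROBAND = 13


@pytest.fixture(scope="session")
def family_frame():
    return four_gen_family()


@pytest.fixture(scope="session")
def family_graph(family_frame):
    return build_pedigree(family_frame)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_founders=60, n_generations=4, rng_seed=3)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_population(small_config)


def smoke_sim_config(seed: int = 5) -> SimConfig:
    """A ~170-person fixture with a familial AD effect strong enough that
    high-risk constellations exist even at this scale."""
    return SimConfig(
        n_founders=14,
        n_generations=4,
        mean_children=2.5,
        familial_ad_multipliers=(25.0, 3.0, 1.0),
        ad_baseline_rate_by_cohort={(1700, 2200): 0.02},
        p_emr_linked=1.0,
        p_dl_linked=1.0,
        rng_seed=seed,
    )
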