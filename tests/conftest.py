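import numpy as np
import pandas as pd
import pytest

from famlong import (
    GompertzMakehamParams,
    SimConfig,
    simulate_study,
    synthesize_collection,
)
from famlong.lifetables import CohortLifetable


@pytest.fixture(scope="session")
def gm_params():
    return GompertzMakehamParams()


@pytest.fixture(scope="session")
def gm_tables(gm_params):
    return synthesize_collection(gm_params)


@pytest.fixture(scope="session")
def const_lifetable():
    """Constant hazard 0.01/year: survival has the closed form exp(-0.01 x)."""
    return CohortLifetable("F", None, np.full(100, 0.01))


@pytest.fixture(scope="session")
def transmission_sim():
    """Medium simulation with a strong transmitted longevity component."""
    return simulate_study(SimConfig(n_families=600, sigma_g2=0.6, sigma_e2=0.2, seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """Medium simulation with no transmitted component."""
    return simulate_study(SimConfig(n_families=400, sigma_g2=0.0, sigma_e2=0.3, seed=12))


@pytest.fixture()
def tiny_family_table():
    """One hand-crafted family: 2 parents, IP + 2 siblings, spouse, 2 children.

    Ages are chosen against the default synthetic lifetable so that the
    father and one sibling are clearly long-lived, the mother is not.
    """
    rows = [
        # person, family, gen, role, sex, by, death, censor, mother, father, spouse,
        # marr, fca, sibsize, order, interval, twin, ses, rel, mab
        dict(person_id=1, family_id=1, generation="F1", role="parent", sex="M",
             birth_year=1780, death_age=90.0, censor_age=np.nan, mother_id=np.nan,
             father_id=np.nan, spouse_id=2, marriage_age=26.0, first_child_age=np.nan,
             sibship_size=np.nan, birth_order=np.nan, birth_interval=np.nan, twin=0,
             ses=3, religion=1, mother_age_at_birth=np.nan),
        dict(person_id=2, family_id=1, generation="F1", role="parent", sex="F",
             birth_year=1782, death_age=60.0, censor_age=np.nan, mother_id=np.nan,
             father_id=np.nan, spouse_id=1, marriage_age=24.0, first_child_age=np.nan,
             sibship_size=np.nan, birth_order=np.nan, birth_interval=np.nan, twin=0,
             ses=3, religion=1, mother_age_at_birth=np.nan),
        dict(person_id=3, family_id=1, generation="F2", role="ip", sex="M",
             birth_year=1808, death_age=70.0, censor_age=np.nan, mother_id=2,
             father_id=1, spouse_id=6, marriage_age=22.0, first_child_age=24.0,
             sibship_size=3, birth_order=1, birth_interval=0.0, twin=0,
             ses=3, religion=1, mother_age_at_birth=26.0),
        dict(person_id=4, family_id=1, generation="F2", role="sibling", sex="F",
             birth_year=1810, death_age=92.0, censor_age=np.nan, mother_id=2,
             father_id=1, spouse_id=np.nan, marriage_age=np.nan, first_child_age=np.nan,
             sibship_size=3, birth_order=2, birth_interval=2.0, twin=0,
             ses=3, religion=1, mother_age_at_birth=28.0),
        dict(person_id=5, family_id=1, generation="F2", role="sibling", sex="M",
             birth_year=1812, death_age=np.nan, censor_age=40.0, mother_id=2,
             father_id=1, spouse_id=np.nan, marriage_age=np.nan, first_child_age=np.nan,
             sibship_size=3, birth_order=3, birth_interval=2.0, twin=0,
             ses=3, religion=1, mother_age_at_birth=30.0),
        dict(person_id=6, family_id=1, generation="F2", role="spouse", sex="F",
             birth_year=1809, death_age=75.0, censor_age=np.nan, mother_id=np.nan,
             father_id=np.nan, spouse_id=3, marriage_age=21.0, first_child_age=23.0,
             sibship_size=4, birth_order=1, birth_interval=0.0, twin=0,
             ses=3, religion=1, mother_age_at_birth=27.0),
        dict(person_id=7, family_id=1, generation="F3", role="child", sex="F",
             birth_year=1832, death_age=68.0, censor_age=np.nan, mother_id=6,
             father_id=3, spouse_id=np.nan, marriage_age=np.nan, first_child_age=np.nan,
             sibship_size=2, birth_order=1, birth_interval=0.0, twin=0,
             ses=3, religion=1, mother_age_at_birth=23.0),
        dict(person_id=8, family_id=1, generation="F3", role="child", sex="M",
             birth_year=1835, death_age=np.nan, censor_age=50.0, mother_id=6,
             father_id=3, spouse_id=np.nan, marriage_age=np.nan, first_child_age=np.nan,
             sibship_size=2, birth_order=2, birth_interval=3.0, twin=0,
             ses=3, religion=1, mother_age_at_birth=26.0),
    ]
    df = pd.DataFrame(rows)
    df["log_frailty"] = 0.0
    return df
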