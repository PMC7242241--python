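import numpy as np
import pytest

from glaucoma_ce.economics import PayoffTable
from glaucoma_ce.markov import (
    CohortConfig,
    DiseaseState,
    LifeTable,
    TransitionModel,
    build_transition_matrix,
)
from glaucoma_ce.model import CostUtilityModel, default_model
from glaucoma_ce.synthetic import fixture_path, gen_life_table


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return gen_life_table()


@pytest.fixture(scope="session")
def transitions() -> TransitionModel:
    return TransitionModel.from_csv(fixture_path("table4_transitions.csv"))


@pytest.fixture(scope="session")
def payoffs() -> PayoffTable:
    return PayoffTable.from_csvs(
        fixture_path("table3_utilities.csv"), fixture_path("table5_costs.csv")
    )


@pytest.fixture(scope="session")
def base_model() -> CostUtilityModel:
    return default_model(include_classes=False)


def constant_mortality_table(q: float, max_age: int = 110, terminal_death: bool = True) -> LifeTable:
    """A flat life table for closed-form checks (q = 1 at the terminal age)."""
    ages = np.arange(0, max_age + 1)
    qs = np.full(ages.shape, q, dtype=float)
    if terminal_death:
        qs[-1] = 1.0
    return LifeTable(ages=ages, q_female=qs, q_male=qs)


def microsimulate(
    strategy,
    transitions,
    life_table,
    config: CohortConfig,
    n_individuals: int,
    seed: int,
) -> np.ndarray:
    """Individual-level simulation with the same per-cycle probabilities.

    An independent oracle for the cohort trace: each of ``n_individuals``
    walks the per-age transition matrix by categorical sampling; returns
    state-occupancy proportions per cycle (rows align with the cohort trace).
    """
    rng = np.random.default_rng(seed)
    states = np.full(n_individuals, int(config.start_state))
    occ = [np.bincount(states, minlength=5) / n_individuals]
    t = 0
    while True:
        age = config.start_age + t
        if age > config.max_age or np.all(states == DiseaseState.DEAD):
            break
        m = build_transition_matrix(age, transitions, life_table, config, strategy)
        cum = np.cumsum(m, axis=1)
        u = rng.random(n_individuals)
        states = (u[:, None] > cum[states]).sum(axis=1)
        t += 1
        occ.append(np.bincount(states, minlength=5) / n_individuals)
    return np.asarray(occ)
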