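"""Lifetime Markov cohort model of primary open-angle glaucoma progression.

The cohort moves through five mutually exclusive states in yearly cycles:
early, moderate and advanced POAG (Hodapp-Parrish-Anderson staging by visual
field mean deviation, thresholds -6 and -12 dB, blindness at a deviation of
-22 dB or worse), blindness, and death.  Progression is strictly forward.
All-cause mortality comes from an age- and sex-specific life table and applies
equally in every living state; within a cycle death is resolved first, the
survivors then stay or progress.

A surgical strategy lowers IOP by some extra amount relative to cataract
surgery alone.  Each mmHg of extra reduction slows visual-field worsening by
0.31% per year; by default that slowing acts multiplicatively on the annual
progression *rate*: p' = 1 - exp(-r * (1 - c)^delta) with r = -ln(1 - p),
which keeps probabilities in [0, 1] and reduces to the identity at zero
effect.  The effect (and the one-off intervention cost) attaches to the
cohort at its first entry into the strategy's application stage and persists
for the remaining lifetime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseState",
    "TransitionModel",
    "LifeTable",
    "CohortConfig",
    "Strategy",
    "CohortTrace",
    "five_year_to_annual",
    "annual_to_five_year",
    "progression_multiplier",
    "mixed_mortality",
    "build_transition_matrix",
    "run_cohort",
]


class DiseaseState(IntEnum):
    EARLY = 0
    MODERATE = 1
    ADVANCED = 2
    BLIND = 3
    DEAD = 4


#: stages with a forward progression transition
PROGRESSIVE_STATES = (DiseaseState.EARLY, DiseaseState.MODERATE, DiseaseState.ADVANCED)
STATE_NAMES = ("early", "moderate", "advanced", "blind", "dead")


def five_year_to_annual(p5: float) -> float:
    """Convert a 5-year transition probability to its annual equivalent.

    Assumes a constant underlying rate: p1 = 1 - (1 - p5)^(1/5).
    """
    if not 0.0 <= p5 <= 1.0:
        raise ValueError("a probability must lie in [0, 1]")
    return 1.0 - (1.0 - p5) ** 0.2


def annual_to_five_year(p1: float) -> float:
    """Inverse of :func:`five_year_to_annual`."""
    if not 0.0 <= p1 <= 1.0:
        raise ValueError("a probability must lie in [0, 1]")
    return 1.0 - (1.0 - p1) ** 5


@dataclass(frozen=True)
class TransitionModel:
    """Annual stay/progress probabilities per POAG stage, before mortality."""

    p_progress: dict[DiseaseState, float]

    def __post_init__(self) -> None:
        for s in PROGRESSIVE_STATES:
            if s not in self.p_progress:
                raise ValueError(f"missing progression probability for {s.name}")
            p = self.p_progress[s]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"progression probability for {s.name} outside [0, 1]")

    def p_stay(self, state: DiseaseState) -> float:
        return 1.0 - self.p_progress[state]

    @classmethod
    def from_stay_progress(
        cls, pairs: dict[str, tuple[float, float]], tol: float = 1e-9
    ) -> "TransitionModel":
        """Build from (stay, progress) pairs; each pair must sum to 1."""
        name_to_state = {"early": DiseaseState.EARLY, "moderate": DiseaseState.MODERATE, "advanced": DiseaseState.ADVANCED}
        p_progress = {}
        for name, (stay, progress) in pairs.items():
            if abs(stay + progress - 1.0) > tol:
                raise ValueError(f"stage {name!r}: stay + progress must equal 1")
            p_progress[name_to_state[name.lower()]] = progress
        return cls(p_progress=p_progress)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionModel":
        """Read a stage table with percent columns ``stay_pct``/``progress_pct``
        (or proportion columns ``p_stay``/``p_progress``)."""
        df = pd.read_csv(path, comment="#")
        if {"stay_pct", "progress_pct"} <= set(df.columns):
            pairs = {r["stage"]: (r["stay_pct"] / 100.0, r["progress_pct"] / 100.0) for _, r in df.iterrows()}
        elif {"p_stay", "p_progress"} <= set(df.columns):
            pairs = {r["stage"]: (r["p_stay"], r["p_progress"]) for _, r in df.iterrows()}
        else:
            raise ValueError("transition table needs stay_pct/progress_pct or p_stay/p_progress columns")
        return cls.from_stay_progress(pairs)


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities by integer age and sex."""

    ages: np.ndarray
    q_female: np.ndarray
    q_male: np.ndarray

    def __post_init__(self) -> None:
        for q in (self.q_female, self.q_male):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("death probabilities must lie in [0, 1]")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life-table ages must be contiguous integers")

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: float, sex: str) -> float:
        if age > self.terminal_age:
            return 1.0
        idx = int(age) - int(self.ages[0])
        if idx < 0:
            raise ValueError(f"age {age} below the life table's first age")
        col = self.q_female if sex == "female" else self.q_male
        return float(col[idx])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        return cls(
            ages=df["age"].to_numpy(dtype=int),
            q_female=df["q_female"].to_numpy(dtype=float),
            q_male=df["q_male"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q_female": self.q_female, "q_male": self.q_male})


@dataclass(frozen=True)
class CohortConfig:
    """Cohort and simulation settings (German POAG base case)."""

    start_age: float = 63.0
    female_fraction: float = 0.442
    start_state: DiseaseState = DiseaseState.EARLY
    cycle_length_years: float = 1.0
    max_age: float = 110.0
    discount_rate: float = 0.03
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        if self.max_age <= self.start_age:
            raise ValueError("max_age must exceed start_age")


@dataclass(frozen=True)
class Strategy:
    """A comparator arm of the decision model.

    ``extra_iop_reduction`` is the additional 1-year IOP drop (mmHg, positive
    = more reduction) relative to cataract surgery alone, from the anchored
    indirect comparison.  ``intervention_cost`` is the one-off surgical cost
    booked when the cohort first enters ``application_stage``.
    """

    name: str
    extra_iop_reduction: float = 0.0
    intervention_cost: float = 0.0
    application_stage: DiseaseState = DiseaseState.MODERATE
    vf_coefficient: float = 0.0031  # per-mmHg fractional VF slowing per year
    vf_mapping: str = "multiplicative"  # or "linear"
    #: SE of the extra IOP reduction; a probabilistic-analysis parameter only
    extra_iop_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.application_stage not in (DiseaseState.MODERATE, DiseaseState.ADVANCED, DiseaseState.EARLY):
            raise ValueError("application_stage must be a living POAG stage")
        if self.vf_mapping not in ("multiplicative", "linear"):
            raise ValueError("vf_mapping must be 'multiplicative' or 'linear'")


def progression_multiplier(
    p: float,
    extra_iop: float,
    coefficient: float = 0.0031,
    mode: str = "multiplicative",
) -> float:
    """Slow an annual progression probability for an extra IOP reduction.

    The probability is moved to the rate scale, r = -ln(1 - p); the rate is
    scaled by (1 - coefficient)^extra_iop (default mode) or by
    (1 - coefficient * extra_iop) (linear mode, clamped at zero), then mapped
    back to a probability.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("a probability must lie in [0, 1]")
    if p == 0.0 or p == 1.0:
        return p  # zero or infinite rate: scaling changes nothing
    if extra_iop == 0.0 or coefficient == 0.0:
        return p  # exact identity, so a null strategy reproduces the reference
    r = -math.log1p(-p)
    if mode == "multiplicative":
        r_new = r * (1.0 - coefficient) ** extra_iop
    elif mode == "linear":
        scale = 1.0 - coefficient * extra_iop
        if scale < 0.0:
            warnings.warn("linear VF mapping scaled the progression rate below zero; clamped to 0")
            scale = 0.0
        r_new = r * scale
    else:
        raise ValueError("mode must be 'multiplicative' or 'linear'")
    return 1.0 - math.exp(-r_new)


def mixed_mortality(age: float, female_fraction: float, table: LifeTable) -> float:
    """Cohort-average annual death probability at ``age``.

    A sex-mix weighted mean of the female and male life-table probabilities;
    ages beyond the terminal age die with certainty.
    """
    if age > table.terminal_age:
        return 1.0
    return female_fraction * table.q(age, "female") + (1.0 - female_fraction) * table.q(age, "male")


def _effective_progress(tm: TransitionModel, strategy: Strategy | None, state: DiseaseState) -> float:
    p = tm.p_progress[state]
    if strategy is None or strategy.extra_iop_reduction == 0.0:
        return p
    if state >= strategy.application_stage:
        return progression_multiplier(
            p, strategy.extra_iop_reduction, strategy.vf_coefficient, strategy.vf_mapping
        )
    return p


def build_transition_matrix(
    age: float,
    transitions: TransitionModel,
    life_table: LifeTable,
    config: CohortConfig,
    strategy: Strategy | None = None,
) -> np.ndarray:
    """Row-stochastic 5x5 transition matrix for one yearly cycle at ``age``.

    Death (probability from :func:`mixed_mortality`) is applied first to every
    living state; the surviving mass splits between staying and progressing.
    The strategy's slowing applies to its application stage and every later
    stage — cohort mass in those stages has, by construction of the forward
    model, already received the intervention.  Blindness transitions only to
    itself or death; there are no backward transitions.
    """
    q = mixed_mortality(age, config.female_fraction, life_table)
    m = np.zeros((5, 5), dtype=float)
    for s in PROGRESSIVE_STATES:
        p_prog = _effective_progress(transitions, strategy, s)
        m[s, DiseaseState.DEAD] = q
        m[s, s + 1] = (1.0 - q) * p_prog
        m[s, s] = (1.0 - q) * (1.0 - p_prog)
    m[DiseaseState.BLIND, DiseaseState.DEAD] = q
    m[DiseaseState.BLIND, DiseaseState.BLIND] = 1.0 - q
    m[DiseaseState.DEAD, DiseaseState.DEAD] = 1.0
    rows = m.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise RuntimeError("transition matrix row does not sum to 1")
    return m


@dataclass
class CohortTrace:
    """State occupancy of the cohort at the start of each yearly cycle.

    ``entry_fraction[t]`` is the cohort mass newly arriving in the strategy's
    application stage at the start of cycle ``t`` — the mass whose one-off
    intervention cost is booked in that cycle.
    """

    occupancy: np.ndarray  # (n_cycles, 5)
    ages: np.ndarray
    entry_fraction: np.ndarray
    capped: bool = False

    def __post_init__(self) -> None:
        rows = self.occupancy.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("every trace row must sum to 1")
        if np.any((self.occupancy < -1e-12) | (self.occupancy > 1 + 1e-12)):
            raise ValueError("occupancies must lie in [0, 1]")
        dead = self.occupancy[:, DiseaseState.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_NAMES)
        df.insert(0, "age", self.ages)
        df["entry_fraction"] = self.entry_fraction
        return df


def run_cohort(
    strategy: Strategy | None,
    transitions: TransitionModel,
    life_table: LifeTable,
    config: CohortConfig,
) -> CohortTrace:
    """Propagate the cohort from ``start_age`` until extinction or ``max_age``.

    The intervention cost accrues to cohort mass at its first arrival in the
    application stage; because the model is strictly forward, the starting
    cohort counts as "arriving" at cycle 0 if it starts in (or past) the
    application stage.
    """
    x = np.zeros(5)
    x[config.start_state] = 1.0
    app = strategy.application_stage if strategy is not None else DiseaseState.MODERATE

    occ = [x.copy()]
    ages = [config.start_age]
    entries = [float(x[app:DiseaseState.DEAD].sum())]  # mass starting at/past the stage
    capped = False

    t = 0
    while True:
        age = config.start_age + t * config.cycle_length_years
        if age > config.max_age:
            if x[DiseaseState.DEAD] < 1.0 - 1e-12:
                capped = True
                warnings.warn("cohort horizon capped at max_age before extinction")
            break
        if x[DiseaseState.DEAD] > 1.0 - 1e-12:
            break
        m = build_transition_matrix(age, transitions, life_table, config, strategy)
        inflow = float(sum(x[s] * m[s, app] for s in range(5) if s != app))
        x = x @ m
        t += 1
        occ.append(x.copy())
        ages.append(config.start_age + t * config.cycle_length_years)
        entries.append(inflow)

    return CohortTrace(
        occupancy=np.array(occ),
        ages=np.array(ages),
        entry_fraction=np.array(entries),
        capped=capped,
    )
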