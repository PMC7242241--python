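"""Costs, utilities, discounting and incremental cost-effectiveness.

State payoffs attach a utility weight (QALY per year) and an annual direct
medical cost (2019 EUR) to each living state of the cohort trace.  Payoffs
accrue at cycle start and are discounted at a single yearly rate applied
after year one, per German appraisal guidelines.  The ICER between an
alternative and the standard arm is the quotient of the discounted cost and
QALY increments, with the usual dominance labels when the increments disagree
in sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import STATE_NAMES, CohortTrace, DiseaseState

__all__ = [
    "StagePayoff",
    "PayoffTable",
    "InterventionCost",
    "CEResult",
    "stage_cost_total",
    "extrapolate_blind_utility",
    "discount_factor",
    "accumulate",
    "icer",
]


@dataclass(frozen=True)
class StagePayoff:
    """Utility weight and annual cost of one health state.

    The SDs parameterize probabilistic-analysis distributions only; they do
    not enter deterministic results.
    """

    state: DiseaseState
    utility: float
    annual_cost: float
    utility_sd: float = 0.0
    annual_cost_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError("utility must lie in [0, 1]")
        if self.annual_cost < 0:
            raise ValueError("annual cost must be non-negative")
        if self.state == DiseaseState.DEAD and (self.utility != 0 or self.annual_cost != 0):
            raise ValueError("the dead state carries zero utility and cost")


@dataclass(frozen=True)
class InterventionCost:
    """One-off surgical cost split into MIGS device/procedure and cataract parts."""

    strategy: str
    migs_procedure: float
    cataract_surgery: float

    @property
    def total(self) -> float:
        return self.migs_procedure + self.cataract_surgery


def stage_cost_total(components: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Total a list of (mean, SD) annual cost components.

    Means add.  SDs are also added linearly, matching how the source cost
    table totals its dispersion columns; the totalled SD only ever feeds the
    probabilistic analysis.
    """
    if any(mean < 0 for mean, _ in components):
        raise ValueError("cost component means must be non-negative")
    mean = float(sum(m for m, _ in components))
    sd = float(sum(s for _, s in components))
    return mean, sd


def extrapolate_blind_utility(stage_utilities: Sequence[float]) -> float:
    """Extrapolate the blindness utility from the three POAG stage utilities.

    An ordinary least-squares line is fitted to (stage index, utility) for
    stages 1..3 and evaluated at index 4, following the utilities' decreasing
    trend.  Returns the unrounded value; reports round to 2 decimals.
    """
    if len(stage_utilities) < 3:
        raise ValueError("need the three POAG stage utilities")
    x = np.arange(1, len(stage_utilities) + 1, dtype=float)
    slope, intercept = np.polyfit(x, np.asarray(stage_utilities, dtype=float), 1)
    return float(intercept + slope * (len(stage_utilities) + 1))


class PayoffTable:
    """Per-state utilities and annual costs for the cohort model."""

    def __init__(self, payoffs: Iterable[StagePayoff]):
        self._by_state: dict[DiseaseState, StagePayoff] = {p.state: p for p in payoffs}
        if DiseaseState.DEAD not in self._by_state:
            self._by_state[DiseaseState.DEAD] = StagePayoff(DiseaseState.DEAD, 0.0, 0.0)
        missing = [s for s in DiseaseState if s not in self._by_state]
        if missing:
            raise ValueError(f"missing payoffs for states: {[s.name for s in missing]}")

    def __getitem__(self, state: DiseaseState) -> StagePayoff:
        return self._by_state[state]

    @property
    def utilities(self) -> np.ndarray:
        return np.array([self._by_state[s].utility for s in DiseaseState])

    @property
    def annual_costs(self) -> np.ndarray:
        return np.array([self._by_state[s].annual_cost for s in DiseaseState])

    def replace(self, state: DiseaseState, **changes) -> "PayoffTable":
        from dataclasses import replace as _replace

        payoffs = [
            _replace(p, **changes) if s == state else p for s, p in self._by_state.items()
        ]
        return PayoffTable(payoffs)

    @classmethod
    def from_csvs(
        cls,
        utilities_csv: str | Path,
        costs_csv: str | Path,
        blind_cost: str | float = "advanced",
    ) -> "PayoffTable":
        """Assemble payoffs from the packaged utility and cost tables.

        The blindness utility is extrapolated from the three stage utilities
        (rounded to 2 decimals, as reported).  The cost table carries no
        blindness row; by default blind patients are assumed to keep consuming
        resources at the advanced-stage level (pass a number to override).
        """
        udf = pd.read_csv(utilities_csv, comment="#").set_index("state")
        cdf = pd.read_csv(costs_csv, comment="#")
        totals = {
            stage: stage_cost_total(list(zip(grp["mean"], grp["sd"])))
            for stage, grp in cdf.groupby("stage")
        }
        stage_u = [float(udf.loc[s, "utility"]) for s in ("early", "moderate", "advanced")]
        blind_u = round(extrapolate_blind_utility(stage_u), 2)
        if isinstance(blind_cost, str):
            blind_c = totals[blind_cost]
        else:
            blind_c = (float(blind_cost), 0.0)
        name_to_state = {"early": DiseaseState.EARLY, "moderate": DiseaseState.MODERATE, "advanced": DiseaseState.ADVANCED}
        payoffs = [
            StagePayoff(
                state=st,
                utility=float(udf.loc[name, "utility"]),
                utility_sd=float(udf.loc[name, "utility_sd"]),
                annual_cost=totals[name][0],
                annual_cost_sd=totals[name][1],
            )
            for name, st in name_to_state.items()
        ]
        payoffs.append(
            StagePayoff(
                state=DiseaseState.BLIND,
                utility=blind_u,
                utility_sd=float(udf.loc["blind", "utility_sd"]),
                annual_cost=blind_c[0],
                annual_cost_sd=blind_c[1],
            )
        )
        return cls(payoffs)


def discount_factor(cycle_index: int, rate: float = 0.03) -> float:
    """Discount multiplier for a 1-based model year; year one is undiscounted."""
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    if cycle_index == 1:
        return 1.0
    return float((1.0 + rate) ** (-(cycle_index - 1)))


def accumulate(
    trace: CohortTrace,
    payoffs: PayoffTable,
    intervention_cost: float = 0.0,
    rate: float = 0.03,
    half_cycle: bool = False,
) -> tuple[float, float]:
    """Discounted lifetime (cost, QALY) totals of a cohort trace.

    Per cycle: occupancy-weighted utility and annual cost, plus the one-off
    intervention cost for the mass newly entering the application stage that
    cycle, each multiplied by that year's discount factor.  State-membership
    payoffs accrue at cycle start by default; ``half_cycle`` switches to the
    mean of cycle-start and cycle-end occupancy.
    """
    if trace.n_cycles == 0:
        return 0.0, 0.0
    occupancy = trace.occupancy
    if half_cycle and trace.n_cycles > 1:
        occupancy = occupancy.copy()
        occupancy[:-1] = 0.5 * (occupancy[:-1] + occupancy[1:])
    n = trace.n_cycles
    years = np.arange(1, n + 1)
    df = np.where(years == 1, 1.0, (1.0 + rate) ** (-(years - 1.0)))
    u = payoffs.utilities
    c = payoffs.annual_costs
    qaly = float(np.sum(df * (occupancy @ u)))
    cost = float(np.sum(df * (occupancy @ c + intervention_cost * trace.entry_fraction)))
    return cost, qaly


@dataclass(frozen=True)
class CEResult:
    """Discounted lifetime outcomes of one strategy versus the reference."""

    strategy: str
    stage: str
    cost: float
    qaly: float
    inc_cost: float
    inc_qaly: float
    icer: float | None
    label: str  # "icer", "dominant", "dominated", "equivalent" or "reference"

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "stage": self.stage,
            "cost": self.cost,
            "inc_cost": self.inc_cost,
            "qaly": self.qaly,
            "inc_qaly": self.inc_qaly,
            "icer": self.icer if self.icer is not None else self.label,
        }


def icer(
    alt: tuple[float, float],
    ref: tuple[float, float],
    strategy: str = "alternative",
    stage: str = "",
) -> CEResult:
    """Incremental cost-effectiveness ratio of ``alt`` versus ``ref``.

    Both are (discounted cost, discounted QALY) pairs computed under identical
    settings.  More costly and more effective yields the quotient; otherwise
    the result is labelled dominant (cheaper, at least as effective),
    dominated (costlier, no more effective) or equivalent.
    """
    inc_cost = alt[0] - ref[0]
    inc_qaly = alt[1] - ref[1]
    if inc_qaly == 0.0 and inc_cost == 0.0:
        value, label = None, "equivalent"
    elif inc_qaly > 0.0 and inc_cost <= 0.0:
        value, label = None, "dominant"
    elif inc_qaly <= 0.0 and inc_cost >= 0.0:
        value, label = None, "dominated"
    else:
        value, label = inc_cost / inc_qaly, "icer"
    return CEResult(
        strategy=strategy,
        stage=stage,
        cost=alt[0],
        qaly=alt[1],
        inc_cost=inc_cost,
        inc_qaly=inc_qaly,
        icer=value,
        label=label,
    )
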