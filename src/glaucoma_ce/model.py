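"""The cost-utility model object tying evidence, cohort dynamics and economics.

:class:`CostUtilityModel` bundles the annual stage-transition probabilities,
state payoffs, life table, cohort settings and the comparator strategies;
``fit()`` runs the lifetime cohort for every strategy at each application
stage and returns a :class:`CostUtilityResults` carrying discounted costs,
QALYs, increments and ICERs versus cataract surgery alone, with a printable
summary table.  Sensitivity analyses (one-way deterministic and Monte Carlo
probabilistic) live in :mod:`glaucoma_ce.sensitivity` and re-run this model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CEResult, PayoffTable, accumulate, icer
from .evidence import EffectEstimate, IndirectComparison, effect_from_ci
from .markov import (
    CohortConfig,
    CohortTrace,
    DiseaseState,
    LifeTable,
    Strategy,
    TransitionModel,
    run_cohort,
)
from .synthetic import fixture_path, gen_life_table

__all__ = [
    "CostUtilityModel",
    "CostUtilityResults",
    "strategies_from_evidence",
    "default_model",
]

REFERENCE_NAME = "cataract_alone"
_STAGE_NAMES = {DiseaseState.MODERATE: "moderate", DiseaseState.ADVANCED: "advanced"}


class CostUtilityModel:
    """Lifetime Markov cost-utility model of MIGS + cataract surgery in POAG.

    Parameters
    ----------
    transitions :
        Annual stay/progress probabilities per POAG stage.
    payoffs :
        Per-state utilities and annual costs.
    life_table :
        Age/sex all-cause mortality.
    strategies :
        The MIGS comparator arms (effect and one-off cost per strategy).
        The reference arm, cataract surgery alone, is implicit: zero extra
        IOP reduction at ``reference_cost``.
    cohort :
        Cohort definition and discounting settings.
    """

    def __init__(
        self,
        transitions: TransitionModel,
        payoffs: PayoffTable,
        life_table: LifeTable,
        strategies: Sequence[Strategy],
        reference_cost: float = 224.84,
        cohort: CohortConfig = CohortConfig(),
    ):
        self.transitions = transitions
        self.payoffs = payoffs
        self.life_table = life_table
        self.strategies = {s.name: s for s in strategies}
        if REFERENCE_NAME in self.strategies:
            raise ValueError("the reference arm is implicit; do not pass it as a strategy")
        self.reference_cost = reference_cost
        self.cohort = cohort

    def with_inputs(self, **changes) -> "CostUtilityModel":
        """A copy of the model with some inputs replaced (for sensitivity runs)."""
        kwargs = dict(
            transitions=self.transitions,
            payoffs=self.payoffs,
            life_table=self.life_table,
            strategies=list(self.strategies.values()),
            reference_cost=self.reference_cost,
            cohort=self.cohort,
        )
        kwargs.update(changes)
        return CostUtilityModel(**kwargs)

    # -- single runs --------------------------------------------------------

    def trace(self, strategy: Strategy | None, stage: DiseaseState) -> CohortTrace:
        if strategy is None:
            strategy = Strategy(name=REFERENCE_NAME, intervention_cost=self.reference_cost)
        strategy = replace(strategy, application_stage=stage)
        return run_cohort(strategy, self.transitions, self.life_table, self.cohort)

    def outcome(self, strategy: Strategy | None, stage: DiseaseState) -> tuple[float, float]:
        """Discounted lifetime (cost, QALY) of one arm applied at ``stage``."""
        cost = strategy.intervention_cost if strategy is not None else self.reference_cost
        tr = self.trace(strategy, stage)
        return accumulate(
            tr,
            self.payoffs,
            intervention_cost=cost,
            rate=self.cohort.discount_rate,
            half_cycle=self.cohort.half_cycle_correction,
        )

    def compare(self, strategy_name: str, stage: DiseaseState) -> CEResult:
        """ICER of one strategy versus cataract alone at one application stage."""
        alt = self.outcome(self.strategies[strategy_name], stage)
        ref = self.outcome(None, stage)
        return icer(alt, ref, strategy=strategy_name, stage=_STAGE_NAMES[stage])

    # -- full fit -----------------------------------------------------------

    def fit(
        self, stages: Sequence[DiseaseState] = (DiseaseState.MODERATE, DiseaseState.ADVANCED)
    ) -> "CostUtilityResults":
        results: list[CEResult] = []
        traces: dict[tuple[str, str], CohortTrace] = {}
        for stage in stages:
            sname = _STAGE_NAMES[stage]
            ref_out = self.outcome(None, stage)
            traces[(REFERENCE_NAME, sname)] = self.trace(None, stage)
            results.append(
                CEResult(
                    strategy=REFERENCE_NAME,
                    stage=sname,
                    cost=ref_out[0],
                    qaly=ref_out[1],
                    inc_cost=0.0,
                    inc_qaly=0.0,
                    icer=None,
                    label="reference",
                )
            )
            for name, strat in self.strategies.items():
                res = icer(self.outcome(strat, stage), ref_out, strategy=name, stage=sname)
                results.append(res)
                traces[(name, sname)] = self.trace(strat, stage)
        return CostUtilityResults(model=self, results=results, traces=traces)


@dataclass
class CostUtilityResults:
    """Fitted lifetime outcomes for every strategy x application stage."""

    model: CostUtilityModel
    results: list[CEResult]
    traces: dict[tuple[str, str], CohortTrace]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def get(self, strategy: str, stage: str) -> CEResult:
        for r in self.results:
            if r.strategy == strategy and r.stage == stage:
                return r
        raise KeyError((strategy, stage))

    def summary(self) -> str:
        """Plain-text results table (costs and QALYs discounted, 2019 EUR)."""
        lines = [
            "Lifetime discounted outcomes vs cataract surgery alone",
            f"{'strategy':<20}{'stage':<10}{'cost':>10}{'inc_cost':>10}{'QALY':>8}{'incQALY':>9}  ICER",
            "-" * 75,
        ]
        for r in self.results:
            icer_s = f"{r.icer:,.2f}" if r.icer is not None else r.label
            lines.append(
                f"{r.strategy:<20}{r.stage:<10}{r.cost:>10.2f}{r.inc_cost:>10.2f}"
                f"{r.qaly:>8.2f}{r.inc_qaly:>9.4f}  {icer_s}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# default construction from packaged evidence


def strategies_from_evidence(
    anchored: Mapping[str, EffectEstimate],
    anchor: EffectEstimate,
    intervention_costs: Mapping[str, float],
    vf_coefficient: float = 0.0031,
    vf_mapping: str = "multiplicative",
    effect_sd: Mapping[str, float] | None = None,
) -> list[Strategy]:
    """Map anchored absolute IOP changes into model strategies.

    The extra reduction versus cataract alone is the anchored effect minus the
    anchor (sign-flipped so that a larger reduction is positive).  The SE of
    the strategy-vs-reference contrast — from ``effect_sd`` when given,
    otherwise recovered from the anchored and anchor SEs — becomes the
    probabilistic-analysis dispersion of the effect.
    """
    effect_sd = dict(effect_sd or {})
    out = []
    for name, eff in anchored.items():
        extra = -(eff.mean - anchor.mean)
        sd = effect_sd.get(name, 0.0)
        if not sd and eff.se is not None and anchor.se is not None and eff.se > anchor.se:
            sd = math.sqrt(eff.se**2 - anchor.se**2)
        out.append(
            Strategy(
                name=name,
                extra_iop_reduction=extra,
                intervention_cost=float(intervention_costs[name]),
                vf_coefficient=vf_coefficient,
                vf_mapping=vf_mapping,
                extra_iop_sd=sd,
            )
        )
    return out


def _published_anchor() -> EffectEstimate:
    df = pd.read_csv(fixture_path("table2_effects.csv"), comment="#").set_index("strategy")
    row = df.loc[REFERENCE_NAME]
    return effect_from_ci(float(row["mean"]), float(row["ci_low"]), float(row["ci_high"]))


def default_itc(rho: float = 0.5, method: str = "random_dl") -> IndirectComparison:
    """The packaged-trial indirect comparison, anchored on the published
    cataract-alone pooled change (the trials report no arm sizes, so pooled
    relative effects are unweighted point estimates)."""
    trials = pd.read_csv(fixture_path("table1_trials.csv"), comment="#")
    groups: dict[str, list[str]] = {}
    for _, r in trials.drop_duplicates("study_id").iterrows():
        groups.setdefault(str(r["strategy"]), []).append(str(r["study_id"]))
    # exploratory class pools on top of the per-device groups
    groups["one_or_two_tmbs"] = groups["one_tmbs"] + groups["two_tmbs"]
    groups["migs"] = groups["one_tmbs"] + groups["two_tmbs"] + groups["is"]
    return IndirectComparison(
        trials, anchor=_published_anchor(), rho=rho, method=method, groups=groups
    )


_DEVICE_COUNT = {"one_tmbs": 1.0, "two_tmbs": 2.0, "is": 1.0}
_CLASS_MEMBERS = {
    "one_or_two_tmbs": ["one_tmbs", "one_tmbs", "two_tmbs"],
    "migs": ["one_tmbs", "one_tmbs", "two_tmbs", "is"],
}


def _default_intervention_costs() -> dict[str, float]:
    df = pd.read_csv(fixture_path("table6_interventions.csv"), comment="#").set_index("strategy")
    totals = (df["migs_procedure"] + df["cataract_surgery"]).to_dict()
    costs = {
        "one_tmbs": totals["one_device"],
        "two_tmbs": totals["two_devices"],
        "is": totals["one_device"],
    }
    # hypothetical class arms: trial-weighted average of member device costs
    for cls, members in _CLASS_MEMBERS.items():
        costs[cls] = float(np.mean([costs[m] for m in members]))
    return costs


def default_model(
    life_table: LifeTable | None = None,
    cohort: CohortConfig = CohortConfig(),
    rho: float = 0.5,
    vf_coefficient: float = 0.0031,
    vf_mapping: str = "multiplicative",
    blind_cost: str | float = "advanced",
    include_classes: bool = False,
) -> CostUtilityModel:
    """Assemble the base-case model from the packaged tables.

    The evidence side runs the anchored indirect comparison on the packaged
    trial summaries; the disease side reads the packaged transition and payoff
    tables; mortality defaults to the synthetic Gompertz-Makeham life table.
    ``include_classes`` adds the exploratory device-class arms.
    """
    itc_res = default_itc(rho=rho).fit()
    names = ["one_tmbs", "two_tmbs", "is"] + (
        ["one_or_two_tmbs", "migs"] if include_classes else []
    )
    anchored = {n: itc_res.effects[n] for n in names}
    # dispersion of each strategy-vs-reference contrast, recovered from the
    # published anchored intervals (variance difference under the Bucher
    # independence assumption); drives the probabilistic analysis only
    published = pd.read_csv(fixture_path("table2_effects.csv"), comment="#").set_index("strategy")
    anchor_var = itc_res.anchor.se**2 if itc_res.anchor.se else 0.0
    effect_sd: dict[str, float] = {}
    for n in names:
        if n in published.index and pd.notna(published.loc[n, "ci_low"]):
            se_anch = (published.loc[n, "ci_high"] - published.loc[n, "ci_low"]) / (2 * 1.959963984540054)
            if se_anch**2 > anchor_var:
                effect_sd[n] = math.sqrt(se_anch**2 - anchor_var)
    strategies = strategies_from_evidence(
        anchored,
        itc_res.anchor,
        _default_intervention_costs(),
        vf_coefficient=vf_coefficient,
        vf_mapping=vf_mapping,
        effect_sd=effect_sd,
    )
    transitions = TransitionModel.from_csv(fixture_path("table4_transitions.csv"))
    payoffs = PayoffTable.from_csvs(
        fixture_path("table3_utilities.csv"),
        fixture_path("table5_costs.csv"),
        blind_cost=blind_cost,
    )
    if life_table is None:
        life_table = gen_life_table()
    ref_cost = float(
        pd.read_csv(fixture_path("table6_interventions.csv"), comment="#")
        .set_index("strategy")
        .loc[REFERENCE_NAME]
        .sum()
    )
    return CostUtilityModel(
        transitions=transitions,
        payoffs=payoffs,
        life_table=life_table,
        strategies=strategies,
        reference_cost=ref_cost,
        cohort=cohort,
    )
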