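"""Deterministic (tornado) and probabilistic (Monte Carlo) sensitivity analyses.

The one-way analysis perturbs each key model input by a fixed fraction
(default +/-20%), re-runs the cost-utility model with all other inputs at
base case, and ranks parameters by the spread of the resulting ICER.

The probabilistic analysis draws every stochastic parameter from a
moment-matched distribution — beta for utilities and transition
probabilities, gamma for annual costs, normal for the IOP effect — re-runs
the full model per iteration, and summarizes the incremental cost/QALY cloud
against a willingness-to-pay threshold, including the cost-effectiveness
acceptability curve (CEAC).  A single master seed spawns one independent
stream per parameter, so adding a parameter never reshuffles the draws of the
others.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CEResult, PayoffTable
from .markov import DiseaseState, Strategy, TransitionModel
from .model import CostUtilityModel

__all__ = [
    "DSAResult",
    "PSAConfig",
    "PSAResult",
    "parameter_values",
    "one_way_dsa",
    "psa",
    "ceac",
]

#: German 2019 willingness-to-pay benchmark: 1 GDP per capita per QALY
DEFAULT_WTP = 43_433.87

_STAGES = {
    "early": DiseaseState.EARLY,
    "moderate": DiseaseState.MODERATE,
    "advanced": DiseaseState.ADVANCED,
    "blind": DiseaseState.BLIND,
}


# ---------------------------------------------------------------------------
# parameter plumbing: a flat name -> value view of the model inputs


def parameter_values(model: CostUtilityModel, strategy: str) -> dict[str, float]:
    """Base-case values of the perturbable inputs for one strategy comparison."""
    vals: dict[str, float] = {}
    for name, st in (("early", DiseaseState.EARLY), ("moderate", DiseaseState.MODERATE), ("advanced", DiseaseState.ADVANCED)):
        vals[f"p_progress_{name}"] = model.transitions.p_progress[st]
    for name, st in _STAGES.items():
        vals[f"utility_{name}"] = model.payoffs[st].utility
        vals[f"cost_{name}"] = model.payoffs[st].annual_cost
    strat = model.strategies[strategy]
    vals["extra_iop_reduction"] = strat.extra_iop_reduction
    vals["intervention_cost"] = strat.intervention_cost
    vals["reference_cost"] = model.reference_cost
    vals["discount_rate"] = model.cohort.discount_rate
    return vals


def _apply_overrides(
    model: CostUtilityModel, strategy: str, overrides: Mapping[str, float]
) -> CostUtilityModel:
    transitions = model.transitions
    payoffs = model.payoffs
    cohort = model.cohort
    strategies = dict(model.strategies)
    reference_cost = model.reference_cost

    p_prog = dict(transitions.p_progress)
    touched = False
    for name, st in (("early", DiseaseState.EARLY), ("moderate", DiseaseState.MODERATE), ("advanced", DiseaseState.ADVANCED)):
        key = f"p_progress_{name}"
        if key in overrides:
            p_prog[st] = float(np.clip(overrides[key], 0.0, 1.0))
            touched = True
    if touched:
        transitions = TransitionModel(p_progress=p_prog)

    for name, st in _STAGES.items():
        changes = {}
        if f"utility_{name}" in overrides:
            changes["utility"] = float(np.clip(overrides[f"utility_{name}"], 0.0, 1.0))
        if f"cost_{name}" in overrides:
            changes["annual_cost"] = max(0.0, float(overrides[f"cost_{name}"]))
        if changes:
            payoffs = payoffs.replace(st, **changes)

    strat = strategies[strategy]
    if "extra_iop_reduction" in overrides:
        strat = replace(strat, extra_iop_reduction=float(overrides["extra_iop_reduction"]))
    if "intervention_cost" in overrides:
        strat = replace(strat, intervention_cost=float(overrides["intervention_cost"]))
    strategies[strategy] = strat
    if "reference_cost" in overrides:
        reference_cost = float(overrides["reference_cost"])
    if "discount_rate" in overrides:
        cohort = replace(cohort, discount_rate=max(0.0, float(overrides["discount_rate"])))

    return model.with_inputs(
        transitions=transitions,
        payoffs=payoffs,
        cohort=cohort,
        strategies=list(strategies.values()),
        reference_cost=reference_cost,
    )


def _compare(model: CostUtilityModel, strategy: str, stage: DiseaseState) -> CEResult:
    return model.compare(strategy, stage)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity


@dataclass(frozen=True)
class DSAResult:
    """ICER range from perturbing one parameter down/up by the DSA fraction."""

    parameter: str
    base_value: float
    low_icer: float | None
    high_icer: float | None
    error: str | None = None

    @property
    def spread(self) -> float:
        if self.low_icer is None or self.high_icer is None:
            return float("nan")
        return abs(self.high_icer - self.low_icer)


def one_way_dsa(
    model: CostUtilityModel,
    strategy: str,
    stage: DiseaseState = DiseaseState.MODERATE,
    delta: float = 0.20,
    parameters: Sequence[str] | None = None,
) -> list[DSAResult]:
    """Tornado analysis: each parameter at (1 - delta) and (1 + delta) times
    its base value, all others at base; ranked by ICER spread (descending).

    Probabilities and utilities are clamped to their domains with a warning;
    a perturbation that makes the model infeasible is recorded as a failed
    scenario rather than silently dropped.  Dominant/dominated scenarios have
    no finite ICER and are carried as None.
    """
    base = parameter_values(model, strategy)
    names = list(parameters) if parameters is not None else list(base)
    out: list[DSAResult] = []
    for name in names:
        v = base[name]
        icers: list[float | None] = []
        err: str | None = None
        for mult in (1.0 - delta, 1.0 + delta):
            value = v * mult
            bounded = name.startswith(("p_progress_", "utility_")) or name == "discount_rate"
            if bounded and not 0.0 <= value <= 1.0:
                warnings.warn(f"{name} perturbed outside its domain; clamped")
            try:
                res = _compare(_apply_overrides(model, strategy, {name: value}), strategy, stage)
                icers.append(res.icer)
            except Exception as exc:  # infeasible scenario: record, don't hide
                err = f"{type(exc).__name__}: {exc}"
                icers.append(None)
        out.append(DSAResult(parameter=name, base_value=v, low_icer=icers[0], high_icer=icers[1], error=err))
    out.sort(key=lambda r: (np.isnan(r.spread), -r.spread if not np.isnan(r.spread) else 0.0))
    return out


def dsa_frame(results: Sequence[DSAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "base_value": r.base_value,
                "low_icer": r.low_icer,
                "high_icer": r.high_icer,
                "spread": r.spread,
                "error": r.error,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings.

    Beta distributions (utilities, probabilities) and gamma distributions
    (costs) are moment-matched to the input mean/SD; the IOP effect is normal.
    Transition probabilities carry no published dispersion, so their SD
    defaults to ``transition_sd_fraction`` of the mean.  A beta SD too large
    to be matched at its mean is shrunk to feasibility with a warning.
    """

    n_iterations: int = 10_000
    seed: int = 20190101
    wtp_threshold: float = DEFAULT_WTP
    transition_sd_fraction: float = 0.10
    vary: tuple[str, ...] = (
        "p_progress",
        "utilities",
        "costs",
        "effect",
    )

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta parameters for a mean in (0, 1)."""
    if not 0.0 < mean < 1.0:
        raise ValueError("beta moment matching needs a mean strictly inside (0, 1)")
    bound = mean * (1.0 - mean)
    var = sd**2
    if var >= bound:
        warnings.warn(f"beta SD {sd:.3g} infeasible at mean {mean:.3g}; shrunk to feasibility")
        var = 0.95 * bound
    kappa = bound / var - 1.0
    return mean * kappa, (1.0 - mean) * kappa


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) for a positive-mean gamma."""
    if mean <= 0:
        raise ValueError("gamma moment matching needs a positive mean")
    return (mean / sd) ** 2, sd**2 / mean


def _param_rng(master_seed: int, name: str) -> np.random.Generator:
    # one independent, name-keyed stream per parameter
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


def _draw(family: str, mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    if family == "beta":
        a, b = _beta_params(mean, sd)
        return rng.beta(a, b, size=n)
    if family == "gamma":
        shape, scale = _gamma_params(mean, sd)
        return rng.gamma(shape, scale, size=n)
    if family == "normal":
        return rng.normal(mean, sd, size=n)
    raise ValueError(f"unknown distribution family {family!r}")


@dataclass
class PSAResult:
    """Monte Carlo sample of incremental outcomes for one strategy/stage."""

    samples: pd.DataFrame  # iteration, inc_cost, inc_qaly
    config: PSAConfig
    strategy: str
    stage: str
    deterministic: CEResult

    def fraction_cost_effective(self, threshold: float | None = None) -> float:
        """Share of iterations cost-effective at the threshold: a positive
        QALY gain bought below the threshold price, or outright dominance."""
        if threshold is None:
            threshold = self.config.wtp_threshold
        inc_c = self.samples["inc_cost"].to_numpy()
        inc_q = self.samples["inc_qaly"].to_numpy()
        ce = (inc_q > 0) & (inc_c <= threshold * inc_q)
        return float(np.mean(ce))

    def ceac(self, thresholds: Sequence[float] | None = None) -> pd.DataFrame:
        if thresholds is None:
            thresholds = np.linspace(0.0, 2.0 * self.config.wtp_threshold, 101)
        return ceac(self.samples, thresholds)

    def summary(self) -> str:
        q = self.samples[["inc_cost", "inc_qaly"]].describe().loc[["mean", "std"]]
        return (
            f"PSA for {self.strategy} ({self.stage} stage), n={len(self.samples)}\n"
            f"mean inc cost {q.loc['mean', 'inc_cost']:.2f} EUR, "
            f"mean inc QALY {q.loc['mean', 'inc_qaly']:.4f}\n"
            f"P(cost-effective at {self.config.wtp_threshold:,.2f} EUR/QALY) = "
            f"{self.fraction_cost_effective():.3f}"
        )


def psa(
    model: CostUtilityModel,
    strategy: str,
    stage: DiseaseState = DiseaseState.MODERATE,
    config: PSAConfig = PSAConfig(),
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Every stochastic parameter is drawn once per iteration (parameters are
    sampled independently; draws are shared between the strategy and the
    reference arm, so parameter uncertainty common to both cancels in the
    increments while the IOP-effect uncertainty does not).
    """
    n = config.n_iterations
    draws: dict[str, np.ndarray] = {}

    if "p_progress" in config.vary:
        for name in ("early", "moderate", "advanced"):
            key = f"p_progress_{name}"
            mean = model.transitions.p_progress[_STAGES[name]]
            sd = config.transition_sd_fraction * mean
            draws[key] = _draw("beta", mean, sd, n, _param_rng(config.seed, key))
    if "utilities" in config.vary:
        for name, st in _STAGES.items():
            key = f"utility_{name}"
            p = model.payoffs[st]
            draws[key] = _draw("beta", p.utility, p.utility_sd, n, _param_rng(config.seed, key))
    if "costs" in config.vary:
        for name, st in _STAGES.items():
            key = f"cost_{name}"
            p = model.payoffs[st]
            if p.annual_cost > 0:
                draws[key] = _draw("gamma", p.annual_cost, p.annual_cost_sd, n, _param_rng(config.seed, key))
    if "effect" in config.vary:
        strat = model.strategies[strategy]
        draws["extra_iop_reduction"] = _draw(
            "normal", strat.extra_iop_reduction, strat.extra_iop_sd, n,
            _param_rng(config.seed, "extra_iop_reduction"),
        )

    rows = np.empty((n, 2))
    for i in range(n):
        overrides = {k: v[i] for k, v in draws.items()}
        res = _compare(_apply_overrides(model, strategy, overrides), strategy, stage)
        rows[i] = (res.inc_cost, res.inc_qaly)

    samples = pd.DataFrame(rows, columns=["inc_cost", "inc_qaly"])
    samples.insert(0, "iteration", np.arange(n))
    stage_name = {DiseaseState.MODERATE: "moderate", DiseaseState.ADVANCED: "advanced"}[stage]
    return PSAResult(
        samples=samples,
        config=config,
        strategy=strategy,
        stage=stage_name,
        deterministic=_compare(model, strategy, stage),
    )


def ceac(samples: pd.DataFrame, thresholds: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a threshold grid."""
    if len(samples) == 0:
        raise ValueError("CEAC needs at least one PSA sample")
    inc_c = samples["inc_cost"].to_numpy()
    inc_q = samples["inc_qaly"].to_numpy()
    probs = [float(np.mean((inc_q > 0) & (inc_c <= t * inc_q))) for t in thresholds]
    return pd.DataFrame({"threshold": list(thresholds), "probability": probs})
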