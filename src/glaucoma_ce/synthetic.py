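"""Synthetic inputs: a Gompertz-Makeham life table and simulated RCT arms.

The national mortality table the cohort model needs is not redistributable,
so a smooth synthetic stand-in is generated from a Gompertz-Makeham hazard,
mu(age) = a + b * exp(c * age), with a multiplicative male excess.  Default
parameters are chosen so that remaining life expectancy at age 63 lands near
contemporary German values (about 22 years for women and 19 for men); the
table is synthetic and makes no attempt to replicate any official table's
entries.

Simulated two-arm trials draw correlated (baseline, follow-up) IOP pairs per
subject with a known true relative effect, and summarize them in the same
per-arm format as the packaged trial fixture — the ground truth for
parameter-recovery checks of the evidence-synthesis code.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .evidence import TrialArm, TwoArmTrial
from .markov import LifeTable

__all__ = [
    "SyntheticLifeTableSpec",
    "SyntheticTrialSpec",
    "gen_life_table",
    "gen_trial",
    "fixtures",
    "fixture_path",
]


@dataclass(frozen=True)
class SyntheticLifeTableSpec:
    """Parameters of the synthetic Gompertz-Makeham life table.

    ``makeham_a`` is the age-independent background hazard per year;
    ``gompertz_b``/``gompertz_c`` the senescent hazard scale and log-slope;
    male hazard is the female hazard times ``male_excess``.
    """

    makeham_a: float = 4.0e-4
    gompertz_b: float = 6.7e-6
    gompertz_c: float = 0.11
    male_excess: float = 1.6
    min_age: int = 0
    terminal_age: int = 110

    def __post_init__(self) -> None:
        if self.gompertz_b <= 0 or self.gompertz_c <= 0 or self.makeham_a < 0:
            raise ValueError("hazard parameters must be positive")
        if self.terminal_age <= self.min_age:
            raise ValueError("terminal_age must exceed min_age")


def gen_life_table(spec: SyntheticLifeTableSpec = SyntheticLifeTableSpec()) -> LifeTable:
    """Deterministically generate the synthetic life table.

    Annual death probabilities are q(age) = 1 - exp(-integrated hazard over
    the year); the terminal age dies with certainty.  Values exceeding 1 are
    clamped with a warning.
    """
    ages = np.arange(spec.min_age, spec.terminal_age + 1)

    def q_from_hazard(b: float) -> np.ndarray:
        # integral of a + b*exp(c*x) over [age, age+1)
        integ = spec.makeham_a + (b / spec.gompertz_c) * (
            np.exp(spec.gompertz_c * (ages + 1.0)) - np.exp(spec.gompertz_c * ages)
        )
        q = 1.0 - np.exp(-integ)
        if np.any(q > 1.0):
            warnings.warn("synthetic hazard produced q > 1 before the terminal age; clamped")
        return np.clip(q, 0.0, 1.0)

    q_f = q_from_hazard(spec.gompertz_b)
    q_m = q_from_hazard(spec.gompertz_b * spec.male_excess)
    q_f[-1] = 1.0
    q_m[-1] = 1.0
    return LifeTable(ages=ages, q_female=q_f, q_male=q_m)


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Ground truth for one simulated two-arm IOP trial.

    ``true_effect`` is the intervention arm's extra mean 1-year IOP change
    relative to control (mmHg; negative = larger reduction).  The control
    arm's own mean change is ``control_effect`` (the cataract-alone effect).
    """

    true_effect: float
    n_per_arm: int = 100
    baseline_mean: float = 19.0
    baseline_sd: float = 3.0
    followup_sd: float = 3.0
    control_effect: float = -2.05
    within_subject_rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")
        if self.baseline_sd <= 0 or self.followup_sd <= 0:
            raise ValueError("SDs must be positive")
        if not -1.0 <= self.within_subject_rho <= 1.0:
            raise ValueError("within_subject_rho must lie in [-1, 1]")


def _simulate_arm(
    rng: np.random.Generator, spec: SyntheticTrialSpec, mean_change: float, label: str
) -> TrialArm:
    cov = spec.within_subject_rho * spec.baseline_sd * spec.followup_sd
    mean = [spec.baseline_mean, spec.baseline_mean + mean_change]
    sigma = [[spec.baseline_sd**2, cov], [cov, spec.followup_sd**2]]
    draws = rng.multivariate_normal(mean, sigma, size=spec.n_per_arm)
    return TrialArm(
        label=label,
        n=spec.n_per_arm,
        mean_baseline=float(draws[:, 0].mean()),
        sd_baseline=float(draws[:, 0].std(ddof=1)),
        mean_followup=float(draws[:, 1].mean()),
        sd_followup=float(draws[:, 1].std(ddof=1)),
    )


def gen_trial(spec: SyntheticTrialSpec, study_id: str = "synthetic") -> TwoArmTrial:
    """Simulate one two-arm trial and return its per-arm summaries."""
    rng = np.random.default_rng(spec.seed)
    intervention = _simulate_arm(
        rng, spec, spec.control_effect + spec.true_effect, f"{study_id}:intervention"
    )
    control = _simulate_arm(rng, spec, spec.control_effect, f"{study_id}:control")
    return TwoArmTrial(
        study_id=study_id,
        intervention=intervention,
        control=control,
        correlation_rho=spec.within_subject_rho,
    )


# ---------------------------------------------------------------------------
# packaged fixtures

_FIXTURE_SHA256 = {
    "table1_trials.csv": "ea5e3ddb847a7eb4eb67b7c32183c8e7192c19197f2c6b58ffd412d616a6e666",
    "table2_effects.csv": "d35da2544a37bb62bb9673cd31551d4fb2710fc3494f71ff4a7280af6510289c",
    "table3_utilities.csv": "586a8721ecd7623df5b441983bc78739fbf691ffd4c3d052842e601b1b61aefc",
    "table4_transitions.csv": "c67b0a556b08132077044e2c50245faaf87ecb69c7abfaa3c75d3b3378928254",
    "table5_costs.csv": "812655109764ffca34e9785b173f7f4d879145875c6ef775abf3cf471ddbda59",
    "table6_interventions.csv": "b1d8b24ad63e00c9ff08b4184836c9bffd9361908f772a9efad15125694e6eb6",
}


def fixture_path(name: str) -> Path:
    """Path of one packaged input table, integrity-checked."""
    if name not in _FIXTURE_SHA256:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURE_SHA256)}")
    path = Path(resources.files("glaucoma_ce").joinpath("data", name))
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"packaged fixture {name!r} failed its integrity check")
    return path


def fixtures() -> dict[str, Path]:
    """All packaged input tables: trial arms, published effects, utilities,
    transition probabilities, stage costs and intervention costs."""
    return {name: fixture_path(name) for name in _FIXTURE_SHA256}
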