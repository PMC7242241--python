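"""Evidence synthesis for anchored indirect treatment comparisons.

Turns per-arm intraocular-pressure (IOP) summaries from two-arm randomized
trials into absolute 1-year IOP-change effects per surgical strategy.  Each
trial compares a MIGS device combined with cataract surgery against cataract
surgery alone, so the shared cataract-alone arm anchors an adjusted indirect
comparison (Bucher): the within-trial relative effect is added to the pooled
absolute change observed under cataract surgery alone, and variances sum under
the independence assumption of the adjusted method.

Where several trials inform one strategy their relative effects are pooled by
inverse-variance meta-analysis, DerSimonian-Laird random effects by default.
Published arm summaries often omit sample sizes; in that case only point
estimates are propagated (an equal-weight mean for pools) unless standard
errors are supplied by configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialArm",
    "TwoArmTrial",
    "EffectEstimate",
    "PooledEffect",
    "arm_change",
    "trial_relative_effect",
    "meta_pool",
    "equal_weight_mean",
    "bucher_anchor",
    "effect_from_ci",
    "trials_from_frame",
    "IndirectComparison",
    "IndirectComparisonResults",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class TrialArm:
    """Summary statistics of one randomized arm (IOP in mmHg)."""

    label: str
    mean_baseline: float
    sd_baseline: float
    mean_followup: float
    sd_followup: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sd_baseline <= 0 or self.sd_followup <= 0:
            raise ValueError(f"arm {self.label!r}: standard deviations must be positive")
        if self.n is not None and self.n < 2:
            raise ValueError(f"arm {self.label!r}: n must be at least 2 when given")
        for fname in ("mean_baseline", "mean_followup"):
            v = getattr(self, fname)
            if v is None or not math.isfinite(v):
                raise ValueError(f"arm {self.label!r}: missing or non-finite {fname}")


@dataclass(frozen=True)
class TwoArmTrial:
    """One randomized trial: MIGS + cataract arm versus cataract-alone arm."""

    study_id: str
    intervention: TrialArm
    control: TrialArm
    #: baseline-to-follow-up correlation used to reconstruct the change-score SD
    correlation_rho: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation_rho <= 1.0:
            raise ValueError("correlation_rho must lie in [-1, 1]")


@dataclass(frozen=True)
class EffectEstimate:
    """A mean IOP change (mmHg; negative = reduction) with optional uncertainty."""

    mean: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.se is not None and self.se < 0:
            raise ValueError("se must be non-negative")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.mean <= self.ci_high):
                raise ValueError("confidence interval must bracket the mean")

    @property
    def variance(self) -> float | None:
        return None if self.se is None else self.se**2


@dataclass(frozen=True)
class PooledEffect(EffectEstimate):
    """Meta-analytic pool of effect estimates.

    ``i2`` is the percentage of between-study variability attributed to
    heterogeneity; it is undefined (None) for single-study pools.
    """

    k: int = 1
    q_stat: float | None = None
    tau2: float | None = None
    i2: float | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.i2 is not None and not 0.0 <= self.i2 <= 100.0:
            raise ValueError("i2 must lie in [0, 100]")


def _with_ci(mean: float, se: float | None) -> tuple[float | None, float | None]:
    if se is None:
        return None, None
    return mean - _Z95 * se, mean + _Z95 * se


def effect_from_ci(mean: float, ci_low: float, ci_high: float) -> EffectEstimate:
    """Back out a normal-approximation SE from a published 95% interval."""
    se = (ci_high - ci_low) / (2.0 * _Z95)
    return EffectEstimate(mean=mean, se=se, ci_low=ci_low, ci_high=ci_high)


def arm_change(arm: TrialArm, rho: float = 0.5) -> EffectEstimate:
    """1-year change from baseline within one arm.

    The change-score SD is reconstructed from the baseline and follow-up SDs
    assuming correlation ``rho``; the SE is available only when the arm size is
    known.
    """
    mean = arm.mean_followup - arm.mean_baseline
    sd_change_sq = (
        arm.sd_baseline**2
        + arm.sd_followup**2
        - 2.0 * rho * arm.sd_baseline * arm.sd_followup
    )
    sd_change = math.sqrt(max(sd_change_sq, 0.0))
    if arm.n is None:
        return EffectEstimate(mean=mean)
    se = sd_change / math.sqrt(arm.n)
    lo, hi = _with_ci(mean, se)
    return EffectEstimate(mean=mean, se=se, ci_low=lo, ci_high=hi)


def trial_relative_effect(trial: TwoArmTrial) -> EffectEstimate:
    """Within-trial difference in IOP change: intervention minus control."""
    a = arm_change(trial.intervention, trial.correlation_rho)
    c = arm_change(trial.control, trial.correlation_rho)
    mean = a.mean - c.mean
    if a.se is None or c.se is None:
        return EffectEstimate(mean=mean)
    se = math.sqrt(a.se**2 + c.se**2)
    lo, hi = _with_ci(mean, se)
    return EffectEstimate(mean=mean, se=se, ci_low=lo, ci_high=hi)


def meta_pool(
    effects: Sequence[EffectEstimate], method: str = "random_dl"
) -> PooledEffect:
    """Inverse-variance pool of effect estimates.

    ``method`` is ``"fixed"`` or ``"random_dl"`` (DerSimonian-Laird additive
    heterogeneity).  A single study passes through unchanged with heterogeneity
    flagged not applicable.
    """
    if method not in ("fixed", "random_dl"):
        raise ValueError(f"unknown pooling method {method!r}")
    k = len(effects)
    if k == 0:
        raise ValueError("cannot pool an empty set of effects")
    if k == 1:
        e = effects[0]
        lo, hi = (e.ci_low, e.ci_high)
        if lo is None and e.se is not None:
            lo, hi = _with_ci(e.mean, e.se)
        return PooledEffect(
            mean=e.mean, se=e.se, ci_low=lo, ci_high=hi, k=1, q_stat=0.0, tau2=0.0, i2=None
        )

    means = np.array([e.mean for e in effects], dtype=float)
    if any(e.se is None or not math.isfinite(e.se) for e in effects):
        raise ValueError("every effect needs a finite SE for pooling; use equal_weight_mean otherwise")
    ses = np.array([e.se for e in effects], dtype=float)
    if np.any(ses == 0.0):
        raise ValueError("an effect with zero SE makes inverse-variance weights degenerate")

    w = 1.0 / ses**2
    mean_fixed = float(np.sum(w * means) / np.sum(w))
    q = float(np.sum(w * (means - mean_fixed) ** 2))
    dof = k - 1
    i2 = max(0.0, 100.0 * (q - dof) / q) if q > 0 else 0.0

    if method == "fixed":
        tau2 = 0.0
        w_star = w
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - dof) / c) if c > 0 else 0.0
        w_star = 1.0 / (ses**2 + tau2)

    mean = float(np.sum(w_star * means) / np.sum(w_star))
    se = float(math.sqrt(1.0 / np.sum(w_star)))
    lo, hi = _with_ci(mean, se)
    return PooledEffect(
        mean=mean, se=se, ci_low=lo, ci_high=hi, k=k, q_stat=q, tau2=tau2, i2=i2
    )


def equal_weight_mean(effects: Sequence[EffectEstimate]) -> PooledEffect:
    """Point-estimate-only pool (arithmetic mean) for effects lacking SEs."""
    if not effects:
        raise ValueError("cannot pool an empty set of effects")
    mean = float(np.mean([e.mean for e in effects]))
    return PooledEffect(mean=mean, se=None, k=len(effects), i2=None)


def bucher_anchor(relative: EffectEstimate, anchor: EffectEstimate) -> EffectEstimate:
    """Anchor a relative effect on the common comparator's absolute change.

    Variances add under the independence assumption of the adjusted indirect
    comparison; when either side lacks a variance only the point estimate is
    returned.
    """
    mean = relative.mean + anchor.mean
    if relative.se is None or anchor.se is None:
        return EffectEstimate(mean=mean)
    se = math.sqrt(relative.se**2 + anchor.se**2)
    lo, hi = _with_ci(mean, se)
    return EffectEstimate(mean=mean, se=se, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# frame I/O and the model object


def trials_from_frame(
    df: pd.DataFrame, rho: float = 0.5, trial_se: Mapping[str, float] | None = None
) -> tuple[list[TwoArmTrial], dict[str, str]]:
    """Build trials from a long table with one row per arm.

    Required columns: ``study_id``, ``arm`` (intervention|control),
    ``mean_baseline``, ``sd_baseline``, ``mean_followup``, ``sd_followup``;
    optional: ``n`` (blank allowed) and ``strategy``.  Returns the trials and a
    study-to-strategy mapping (empty if no strategy column).
    """
    required = {"study_id", "arm", "mean_baseline", "sd_baseline", "mean_followup", "sd_followup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    trials: list[TwoArmTrial] = []
    strategy_of: dict[str, str] = {}
    for study_id, grp in df.groupby("study_id", sort=False):
        arms: dict[str, TrialArm] = {}
        for _, row in grp.iterrows():
            n = row.get("n")
            n = None if n is None or (isinstance(n, float) and math.isnan(n)) else int(n)
            arms[str(row["arm"])] = TrialArm(
                label=f"{study_id}:{row['arm']}",
                mean_baseline=float(row["mean_baseline"]),
                sd_baseline=float(row["sd_baseline"]),
                mean_followup=float(row["mean_followup"]),
                sd_followup=float(row["sd_followup"]),
                n=n,
            )
        if set(arms) != {"intervention", "control"}:
            raise ValueError(f"study {study_id!r} must have exactly one intervention and one control arm")
        trials.append(
            TwoArmTrial(study_id=str(study_id), intervention=arms["intervention"], control=arms["control"], correlation_rho=rho)
        )
        if "strategy" in grp.columns:
            strategy_of[str(study_id)] = str(grp["strategy"].iloc[0])
    if trial_se:
        pass  # SEs are attached at relative-effect level by IndirectComparison
    return trials, strategy_of


@dataclass
class IndirectComparisonResults:
    """Fitted anchored effects.

    ``effects`` maps strategy name to the anchored absolute 1-year IOP change;
    ``relative`` holds the per-strategy pooled relative effect versus the
    common comparator; ``per_trial`` the within-trial relative effects.
    """

    anchor: EffectEstimate
    effects: dict[str, EffectEstimate]
    relative: dict[str, PooledEffect]
    per_trial: dict[str, EffectEstimate]
    method: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": "cataract_alone",
                "mean": self.anchor.mean,
                "ci_low": self.anchor.ci_low,
                "ci_high": self.anchor.ci_high,
                "k": getattr(self.anchor, "k", None),
                "i2": getattr(self.anchor, "i2", None),
            }
        ]
        for name, eff in self.effects.items():
            rel = self.relative[name]
            rows.append(
                {
                    "strategy": name,
                    "mean": eff.mean,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "k": rel.k,
                    "i2": rel.i2,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Anchored 1-year IOP change from baseline (mmHg)", "=" * 56]
        for _, r in df.iterrows():
            ci = ""
            if pd.notna(r["ci_low"]):
                ci = f"  95% CI ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
            i2 = "" if pd.isna(r["i2"]) else f"  I2={r['i2']:.0f}%"
            k = "" if pd.isna(r["k"]) else f"  k={int(r['k'])}"
            lines.append(f"{r['strategy']:<20}{r['mean']:8.2f}{ci}{k}{i2}")
        return "\n".join(lines)


class IndirectComparison:
    """Anchored indirect comparison of trial strategies via a shared comparator.

    Parameters
    ----------
    trials :
        The two-arm trials, or a long DataFrame accepted by
        :func:`trials_from_frame`.
    anchor :
        Absolute 1-year IOP change under the common comparator (cataract
        surgery alone).  If None it is estimated from the control arms: by
        meta-analysis when arm sizes are known, otherwise as an unweighted
        mean of control-arm changes.
    groups :
        Strategy name -> study_ids pooled for that strategy.  Defaults to the
        ``strategy`` column of the input frame (one group per value).
    trial_se :
        Optional study_id -> SE (mmHg) of the within-trial relative effect,
        for when arm sizes are unpublished but an SE is available elsewhere.
    """

    def __init__(
        self,
        trials: Sequence[TwoArmTrial] | pd.DataFrame,
        anchor: EffectEstimate | None = None,
        rho: float = 0.5,
        method: str = "random_dl",
        groups: Mapping[str, Sequence[str]] | None = None,
        trial_se: Mapping[str, float] | None = None,
    ):
        if isinstance(trials, pd.DataFrame):
            trials, strategy_of = trials_from_frame(trials, rho=rho)
            if groups is None and strategy_of:
                groups = {}
                for sid, strat in strategy_of.items():
                    groups.setdefault(strat, []).append(sid)
        self.trials = list(trials)
        if not self.trials:
            raise ValueError("at least one trial is required")
        if groups is None:
            groups = {t.study_id: [t.study_id] for t in self.trials}
        self.groups = {k: list(v) for k, v in groups.items()}
        self.anchor = anchor
        self.rho = rho
        self.method = method
        self.trial_se = dict(trial_se or {})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "IndirectComparison":
        return cls(df, **kwargs)

    def _relative_effects(self) -> dict[str, EffectEstimate]:
        out: dict[str, EffectEstimate] = {}
        for t in self.trials:
            eff = trial_relative_effect(t)
            se = self.trial_se.get(t.study_id)
            if se is not None:
                lo, hi = _with_ci(eff.mean, se)
                eff = EffectEstimate(mean=eff.mean, se=se, ci_low=lo, ci_high=hi)
            out[t.study_id] = eff
        return out

    def _pool(self, effects: Sequence[EffectEstimate]) -> PooledEffect:
        if len(effects) > 1 and any(e.se is None for e in effects):
            return equal_weight_mean(effects)
        return meta_pool(effects, method=self.method)

    def fit(self) -> IndirectComparisonResults:
        per_trial = self._relative_effects()
        anchor = self.anchor
        if anchor is None:
            controls = [arm_change(t.control, self.rho) for t in self.trials]
            anchor = self._pool(controls)
        relative: dict[str, PooledEffect] = {}
        anchored: dict[str, EffectEstimate] = {}
        for name, members in self.groups.items():
            effs = [per_trial[sid] for sid in members]
            pooled = self._pool(effs)
            relative[name] = pooled
            anchored[name] = bucher_anchor(pooled, anchor)
        return IndirectComparisonResults(
            anchor=anchor, effects=anchored, relative=relative, per_trial=per_trial, method=self.method
        )
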