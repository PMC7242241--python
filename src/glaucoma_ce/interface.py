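"""Configuration handling and pipeline orchestration.

An :class:`AnalysisConfig` collects every tunable of the analysis — file
paths (defaulting to the packaged tables and the synthetic life table),
evidence-synthesis settings, cohort definition, the visual-field mapping, and
the probabilistic-analysis block — with validation and lossless YAML
round-tripping.  :func:`run_pipeline` executes the full chain (indirect
comparison, cohort runs for every strategy and stage, ICER table, optional
tornado/PSA/CEAC) and writes the report files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .economics import PayoffTable
from .markov import CohortConfig, DiseaseState, LifeTable, TransitionModel
from .model import CostUtilityModel, default_itc, default_model
from .sensitivity import DEFAULT_WTP, PSAConfig, dsa_frame, one_way_dsa, psa
from .synthetic import gen_life_table

__all__ = ["AnalysisConfig", "PSASettings", "load_config", "save_config", "run_pipeline"]

log = logging.getLogger("glaucoma_ce")


@dataclass
class PSASettings:
    n_iterations: int = 10_000
    seed: int = 20190101
    wtp_threshold: float = DEFAULT_WTP
    transition_sd_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("psa.n_iterations must be at least 1")

    def to_psa_config(self) -> PSAConfig:
        return PSAConfig(
            n_iterations=self.n_iterations,
            seed=self.seed,
            wtp_threshold=self.wtp_threshold,
            transition_sd_fraction=self.transition_sd_fraction,
        )


@dataclass
class AnalysisConfig:
    """Every analysis setting, with the base-case values as defaults.

    ``None`` paths mean "use the packaged table" (or the synthetic life
    table).  All defaults are logged with their provenance when the config is
    loaded.
    """

    trials_csv: str | None = None
    transitions_csv: str | None = None
    utilities_csv: str | None = None
    costs_csv: str | None = None
    interventions_csv: str | None = None
    life_table_csv: str | None = None
    rho: float = 0.5
    meta_method: str = "random_dl"
    vf_mapping: str = "multiplicative"
    vf_coefficient: float = 0.0031
    discount_rate: float = 0.03
    start_age: float = 63.0
    female_fraction: float = 0.442
    max_age: float = 110.0
    application_stages: list[str] = field(default_factory=lambda: ["moderate", "advanced"])
    include_classes: bool = True
    blind_cost: str = "advanced"
    half_cycle_correction: bool = False
    psa: PSASettings = field(default_factory=PSASettings)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.psa, dict):
            self.psa = PSASettings(**self.psa)
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.meta_method not in ("fixed", "random_dl"):
            raise ValueError("meta_method must be 'fixed' or 'random_dl'")
        if self.vf_mapping not in ("multiplicative", "linear"):
            raise ValueError("vf_mapping must be 'multiplicative' or 'linear'")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        bad = set(self.application_stages) - {"moderate", "advanced"}
        if bad:
            raise ValueError(f"unknown application stages: {sorted(bad)}")
        for pathfield in ("trials_csv", "transitions_csv", "utilities_csv", "costs_csv", "interventions_csv", "life_table_csv"):
            p = getattr(self, pathfield)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{pathfield}: no such file {p!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            start_age=self.start_age,
            female_fraction=self.female_fraction,
            max_age=self.max_age,
            discount_rate=self.discount_rate,
            half_cycle_correction=self.half_cycle_correction,
        )

    def build_model(self) -> CostUtilityModel:
        life_table = (
            LifeTable.from_csv(self.life_table_csv)
            if self.life_table_csv
            else gen_life_table()
        )
        model = default_model(
            life_table=life_table,
            cohort=self.cohort_config(),
            rho=self.rho,
            vf_coefficient=self.vf_coefficient,
            vf_mapping=self.vf_mapping,
            blind_cost=self.blind_cost,
            include_classes=self.include_classes,
        )
        # user-supplied tables override the packaged ones
        if self.transitions_csv:
            model = model.with_inputs(transitions=TransitionModel.from_csv(self.transitions_csv))
        if self.utilities_csv or self.costs_csv:
            from .synthetic import fixture_path

            model = model.with_inputs(
                payoffs=PayoffTable.from_csvs(
                    self.utilities_csv or fixture_path("table3_utilities.csv"),
                    self.costs_csv or fixture_path("table5_costs.csv"),
                    blind_cost=self.blind_cost,
                )
            )
        return model


_FIELD_NAMES = {f.name for f in dataclasses.fields(AnalysisConfig)}


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load and validate a YAML config; unknown keys are an error.

    Every field left at its default is logged with provenance "default"."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**data)
    for name in sorted(_FIELD_NAMES):
        source = "user" if name in data else "default"
        log.info("config %s = %r (%s)", name, getattr(cfg, name), source)
    return cfg


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


_STAGE_OF = {"moderate": DiseaseState.MODERATE, "advanced": DiseaseState.ADVANCED}


def run_pipeline(
    cfg: AnalysisConfig,
    run_dsa: bool = False,
    run_psa: bool = False,
    psa_strategy: str = "two_tmbs",
    psa_stage: str = "moderate",
) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Writes ``effects.csv`` (anchored IOP changes), ``results.csv`` (lifetime
    outcomes and ICERs) and, on request, ``tornado.csv``, ``psa_samples.csv``
    and ``ceac.csv`` plus a JSON summary.  Outputs are staged in a temporary
    directory and moved into place only on success, so a failing stage leaves
    no partial report.
    """
    outdir = Path(cfg.output_dir)
    staging = Path(tempfile.mkdtemp(prefix="glaucoma_ce_"))
    written: dict[str, Path] = {}
    try:
        log.info("stage: indirect treatment comparison")
        if cfg.trials_csv:
            from .evidence import IndirectComparison
            from .model import _published_anchor

            trials = pd.read_csv(cfg.trials_csv, comment="#")
            itc = IndirectComparison(trials, anchor=_published_anchor(), rho=cfg.rho, method=cfg.meta_method)
        else:
            itc = default_itc(rho=cfg.rho, method=cfg.meta_method)
        itc_res = itc.fit()
        itc_res.to_frame().to_csv(staging / "effects.csv", index=False)

        log.info("stage: cohort model")
        model = cfg.build_model()
        stages = [_STAGE_OF[s] for s in cfg.application_stages]
        fitted = model.fit(stages=stages)
        fitted.to_frame().round(2).to_csv(staging / "results.csv", index=False)

        summary: dict[str, Any] = {
            "anchored_effects_mmhg": {k: round(v.mean, 2) for k, v in itc_res.effects.items()},
            "results": fitted.to_frame().round(4).to_dict(orient="records"),
        }

        if run_dsa:
            log.info("stage: one-way sensitivity")
            tornado = dsa_frame(one_way_dsa(model, psa_strategy, _STAGE_OF[psa_stage]))
            tornado.to_csv(staging / "tornado.csv", index=False)
        if run_psa:
            log.info("stage: probabilistic sensitivity")
            res = psa(model, psa_strategy, _STAGE_OF[psa_stage], cfg.psa.to_psa_config())
            res.samples.to_csv(staging / "psa_samples.csv", index=False)
            res.ceac().to_csv(staging / "ceac.csv", index=False)
            summary["psa_fraction_cost_effective"] = res.fraction_cost_effective()

        with open(staging / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)

        outdir.mkdir(parents=True, exist_ok=True)
        for f in staging.iterdir():
            target = outdir / f.name
            shutil.move(str(f), target)
            written[f.name] = target
        return written
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        shutil.rmtree(staging, ignore_errors=True)
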