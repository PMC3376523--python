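"""Strict run configuration: schema, loaders, and domain-object builders.

Every reproduced number must be traceable to a logged parameter, so the
schema is strict — unknown keys are rejected, and there is no silent
defaulting beyond the explicit field defaults below (which encode the
primary analysis: $45/h wages with 17% on-costs, the itemized Table-of-
costs structures, a $250 fee, 20-capacity classes).
"""
from __future__ import annotations

from importlib import resources
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .money import money
from . import cost_model, breakeven, cea, cba, synthetic_cohort


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CostItemConfig(_Strict):
    name: str
    amount: float
    recurrence: str
    payer: str = "provider"


class CostStructureConfig(_Strict):
    mode: str
    class_capacity: int = 20
    facilitator_hours: float
    facilitator_rate: float
    items: List[CostItemConfig]


class WagePolicyConfig(_Strict):
    base_rate: float = 45.0
    on_cost_multiplier: float = 1.17
    penalty_loading: float = 1.5


class TimeProfileConfig(_Strict):
    contact_hours_f2f: float = 8.0
    extra_hours_web: float = 1.6
    participant_total_hours_f2f: float = 12.0
    participant_total_hours_web: float = 14.4


class SweepAxisConfig(_Strict):
    axis: str
    values: List[float]


class BreakevenConfig(_Strict):
    enrollment_fee: float = 250.0
    max_enrollments: int = 60
    sweeps: Dict[str, List[SweepAxisConfig]] = Field(default_factory=dict)


class CEAScenarioConfig(_Strict):
    label: str
    timing: str
    fee_paid_by_service: bool
    backfill: bool = False


class CEAConfig(_Strict):
    class_size: int = 20
    enrollment_fee: float = 250.0
    alternative_fee_factor: Optional[float] = 2.1
    include_equal_attrition: bool = True
    scenarios: List[CEAScenarioConfig]


class CBAScenarioConfig(_Strict):
    label: str
    timing: str = "working_hours"
    internet_variant: str = "broadband"
    fee_scale: float = 1.0
    all_costs_scale: float = 1.0
    fee_paid_by_participant: bool = True


class CBAConfig(_Strict):
    fee: float = 250.0
    benefit_context: int = 3
    scenarios: List[CBAScenarioConfig]


class ArmSpecConfig(_Strict):
    n_enrolled: int
    completion_probability: float
    grade_mean: float
    grade_sd: float
    wtp_mean: Dict[int, float]
    wtp_sd: Dict[int, float]
    wtp_spearman: Dict[int, float]
    wtp_missing_rate: float = 0.0
    satisfaction_missing_rate: float = 0.0
    satisfaction_levels: int = 5


class CohortConfig(_Strict):
    seed: int = 0
    arms: Dict[str, ArmSpecConfig]


class RunConfig(_Strict):
    """Top-level pipeline configuration (strict schema)."""

    cost_structures: Dict[str, CostStructureConfig]
    wage_policy: WagePolicyConfig = Field(default_factory=WagePolicyConfig)
    time_profile: TimeProfileConfig = Field(default_factory=TimeProfileConfig)
    breakeven: BreakevenConfig = Field(default_factory=BreakevenConfig)
    cea: CEAConfig
    cba: CBAConfig
    cohort: Optional[CohortConfig] = None
    participant_table: Optional[str] = None
    output_dir: str = "results"
    seed: int = 0

    @model_validator(mode="after")
    def _check_cohort_source(self):
        if self.cohort is None and self.participant_table is None:
            raise ValueError(
                "config requires either a 'cohort' spec or a "
                "'participant_table' path"
            )
        missing = set(cost_model.MODES) - set(self.cost_structures)
        if missing:
            raise ValueError(f"cost_structures missing modes: {sorted(missing)}")
        return self


# Loaders --------------------------------------------------------------------


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def load_default_config() -> RunConfig:
    """The packaged primary-analysis configuration."""
    ref = resources.files("eduecon").joinpath("data/default_config.yaml")
    raw = yaml.safe_load(ref.read_text())
    return RunConfig.model_validate(raw)


# Domain-object builders -----------------------------------------------------


def build_wage_policy(cfg: WagePolicyConfig) -> cost_model.WagePolicy:
    return cost_model.WagePolicy(
        base_rate=money(cfg.base_rate),
        on_cost_multiplier=money(cfg.on_cost_multiplier),
        penalty_loading=money(cfg.penalty_loading),
    )


def build_time_profile(cfg: TimeProfileConfig) -> cost_model.TimeProfile:
    return cost_model.TimeProfile(
        contact_hours_f2f=cfg.contact_hours_f2f,
        extra_hours_web=cfg.extra_hours_web,
        participant_total_hours_f2f=cfg.participant_total_hours_f2f,
        participant_total_hours_web=cfg.participant_total_hours_web,
    )


def build_cost_structure(cfg: CostStructureConfig) -> cost_model.DeliveryCostStructure:
    items = tuple(
        cost_model.CostItem(
            name=i.name, amount=money(i.amount), recurrence=i.recurrence, payer=i.payer
        )
        for i in cfg.items
    )
    return cost_model.DeliveryCostStructure(
        mode=cfg.mode,
        items=items,
        class_capacity=cfg.class_capacity,
        facilitator_hours=cfg.facilitator_hours,
        facilitator_rate=money(cfg.facilitator_rate),
    )


def build_breakeven_scenario(
    structure: cost_model.DeliveryCostStructure, cfg: BreakevenConfig
) -> breakeven.BreakEvenScenario:
    return breakeven.BreakEvenScenario(
        fixed_per_class=structure.fixed_total,
        variable_per_participant=structure.variable_total,
        enrollment_fee=money(cfg.enrollment_fee),
        class_capacity=structure.class_capacity,
        max_enrollments=cfg.max_enrollments,
    )


def build_cea_scenarios(
    cfg: CEAConfig,
    policy: cost_model.WagePolicy,
    time_profile: cost_model.TimeProfile,
) -> list:
    return [
        cea.CEAScenario(
            label=s.label,
            timing=s.timing,
            fee_paid_by_service=s.fee_paid_by_service,
            backfill=s.backfill,
            enrolled=cfg.class_size,
            enrollment_fee=money(cfg.enrollment_fee),
            in_work_hours=time_profile.in_work_hours(),
            wage_policy=policy,
        )
        for s in cfg.scenarios
    ]


def build_cba_scenarios(cfg: CBAConfig) -> list:
    return [
        cba.CBAScenario(
            label=s.label,
            timing=s.timing,
            internet_variant=s.internet_variant,
            fee_scale=s.fee_scale,
            all_costs_scale=s.all_costs_scale,
            fee_paid_by_participant=s.fee_paid_by_participant,
        )
        for s in cfg.scenarios
    ]


def build_cohort_spec(
    cfg: CohortConfig, seed: Optional[int] = None
) -> synthetic_cohort.SyntheticCohortSpec:
    arms = {
        arm: synthetic_cohort.ArmSpec(
            n_enrolled=a.n_enrolled,
            completion_probability=a.completion_probability,
            grade_mean=a.grade_mean,
            grade_sd=a.grade_sd,
            wtp_mean=dict(a.wtp_mean),
            wtp_sd=dict(a.wtp_sd),
            wtp_spearman=dict(a.wtp_spearman),
            wtp_missing_rate=a.wtp_missing_rate,
            satisfaction_missing_rate=a.satisfaction_missing_rate,
            satisfaction_levels=a.satisfaction_levels,
        )
        for arm, a in cfg.arms.items()
    }
    return synthetic_cohort.SyntheticCohortSpec(
        arms=arms, seed=cfg.seed if seed is None else seed
    )
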