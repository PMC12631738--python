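"""Structured model configuration: schema, validation and resolution.

Every economic input (unit drug costs, dosing rules, utilities, adverse-event
blocks, discount rate, body metrics, subsequent-treatment proportions and
regimen mix) enters through a YAML document validated against the pydantic
schema below; nothing is hard-coded.  Uncertain quantities are written as
``{base, low, high, dist}`` blocks, from which the sensitivity analyses draw
their ranges and sampling distributions.

``resolve_inputs`` flattens a validated configuration (plus an optional
``{parameter name: value}`` override map, used by the DSA and PSA) into the
plain-number :class:`~psmcea.valuation.ModelInputs` consumed by the valuation
layer.  Parameter names are dotted paths such as ``drugs.pembrolizumab.
unit_cost`` or ``ae.incidence.PEM.diarrhea``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import EngineConfig
from .kmdata import DigitizedCurve, RiskTable
from .valuation import ARMS, AdverseEvent, DrugSpec, ModelInputs, PatientProfile

__all__ = [
    "Param",
    "ModelConfig",
    "ModelBundle",
    "ParamDistribution",
    "load_config",
    "resolve_inputs",
    "parameter_specs",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Param(_Section):
    """An uncertain scalar: base value, range, and PSA sampling family."""

    base: float
    low: Optional[float] = None
    high: Optional[float] = None
    dist: Literal["gamma", "beta", "fixed"] = "fixed"

    @model_validator(mode="after")
    def _check(self):
        if (self.low is None) != (self.high is None):
            raise ValueError("low and high must be given together")
        if self.low is not None and not self.low <= self.base <= self.high:
            raise ValueError(f"require low <= base <= high, got {self.low}, {self.base}, {self.high}")
        if self.dist == "beta" and not 0.0 < self.base < 1.0:
            raise ValueError("beta-distributed parameters must have base in (0, 1)")
        return self


class EngineSection(_Section):
    cycle_length_days: float = 21.0
    horizon_years: float = 30.0
    discount_rate: Param = Param(base=0.05, low=0.0, high=0.08, dist="fixed")


class PatientSection(_Section):
    weight_kg: Param = Param(base=60.0, low=48.0, high=72.0, dist="fixed")
    bsa_m2: Param = Param(base=1.6, low=1.28, high=1.92, dist="fixed")


class UtilitiesSection(_Section):
    pfs: Param
    pd: Param

    @model_validator(mode="after")
    def _bounds(self):
        for name in ("pfs", "pd"):
            p = getattr(self, name)
            if not 0.0 <= p.base <= 1.0:
                raise ValueError(f"utility {name} must lie in [0, 1], got {p.base}")
        return self


class CostsSection(_Section):
    follow_up_per_cycle: Param
    administration_per_cycle: Param
    end_of_life: Param
    best_supportive_care_per_cycle: Param


class DrugConfig(_Section):
    unit_size_mg: float
    unit_cost: Param
    dose_rule: Literal["flat_mg", "per_kg", "per_m2"]
    dose_amount: float
    admins_per_cycle: int = 1
    loading_per_kg: Optional[float] = None
    line: Literal["first", "second"] = "first"
    arms: Optional[list[str]] = None  # None = both arms
    component: Literal["backbone", "fp", "capox", "second"] = "backbone"
    cycle_days: float = 21.0


class FirstLineSection(_Section):
    cap_cycles: int = 35
    chemo_mix: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _mix_sums(self):
        for arm, mix in self.chemo_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"chemo_mix for arm {arm} sums to {total}, not 1")
        return self


class SubsequentSection(_Section):
    rate: dict[str, Param]

    @model_validator(mode="after")
    def _rate_bounds(self):
        for arm, p in self.rate.items():
            if not 0.0 <= p.base <= 1.0:
                raise ValueError(f"subsequent-treatment rate for {arm} out of [0, 1]")
        return self


class AdverseEventsSection(_Section):
    costs: dict[str, Param]
    disutilities: dict[str, Param]
    incidence: dict[str, dict[str, Param]]

    @model_validator(mode="after")
    def _names_known(self):
        for arm, block in self.incidence.items():
            for name in block:
                if name not in self.costs or name not in self.disutilities:
                    raise ValueError(f"AE {name!r} ({arm}) lacks a cost or disutility entry")
        return self


class AssistanceSection(_Section):
    mode: Literal["off", "free_after_n"] = "off"
    free_after_n: int = 4


class PDCostingSection(_Section):
    bsc_additive: bool = False


class SelectionSection(_Section):
    criterion: Literal["aic", "bic"] = "aic"
    family: Optional[str] = None  # force a family instead of ranking


class CurvesSection(_Section):
    fixture: Optional[str] = None
    curves_csv: Optional[str] = None
    risk_csv: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self):
        from_files = self.curves_csv is not None and self.risk_csv is not None
        if self.fixture is None and not from_files:
            raise ValueError("curves must name a fixture or both curves_csv and risk_csv")
        if self.fixture is not None and (self.curves_csv or self.risk_csv):
            raise ValueError("give either a fixture name or CSV paths, not both")
        return self


class ModelConfig(_Section):
    schema_version: int = 1
    population: Literal["total", "cps_ge_1"] = "total"
    wtp: float = Field(gt=0)
    engine: EngineSection = EngineSection()
    patient: PatientSection = PatientSection()
    utilities: UtilitiesSection
    costs: CostsSection
    drugs: dict[str, DrugConfig]
    first_line: FirstLineSection
    subsequent_treatment: SubsequentSection
    adverse_events: AdverseEventsSection
    assistance: AssistanceSection = AssistanceSection()
    pd_costing: PDCostingSection = PDCostingSection()
    selection: SelectionSection = SelectionSection()
    curves: CurvesSection

    @model_validator(mode="after")
    def _arms_covered(self):
        for arm in ARMS:
            if arm not in self.first_line.chemo_mix:
                raise ValueError(f"first_line.chemo_mix missing arm {arm}")
            if arm not in self.subsequent_treatment.rate:
                raise ValueError(f"subsequent_treatment.rate missing arm {arm}")
        return self


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ModelConfig.model_validate(raw)


@dataclass(frozen=True)
class ModelBundle:
    """A validated configuration plus the four digitized curves per arm."""

    config: ModelConfig
    curves: dict[tuple[str, str], DigitizedCurve]
    risk_tables: dict[tuple[str, str], RiskTable]

    def __post_init__(self):
        for endpoint in ("OS", "PFS"):
            for arm in ARMS:
                key = (endpoint, arm)
                if key not in self.curves:
                    raise ValueError(f"bundle is missing the {endpoint} curve for arm {arm}")
                if key not in self.risk_tables:
                    raise ValueError(f"bundle is missing the {endpoint} risk table for arm {arm}")

    @property
    def population(self) -> str:
        return self.config.population


# -- parameter resolution ----------------------------------------------------


@dataclass(frozen=True)
class ParamDistribution:
    """A named uncertain parameter as seen by the sensitivity analyses."""

    name: str
    base: float
    low: float | None
    high: float | None
    family: str  # gamma | beta | fixed
    in_psa: bool
    in_dsa: bool


def _walk_params(cfg: ModelConfig):
    """Yield (dotted name, Param, psa_eligible) over every uncertain input."""
    yield "engine.discount_rate", cfg.engine.discount_rate
    yield "patient.weight_kg", cfg.patient.weight_kg
    yield "patient.bsa_m2", cfg.patient.bsa_m2
    yield "utilities.pfs", cfg.utilities.pfs
    yield "utilities.pd", cfg.utilities.pd
    yield "costs.follow_up_per_cycle", cfg.costs.follow_up_per_cycle
    yield "costs.administration_per_cycle", cfg.costs.administration_per_cycle
    yield "costs.end_of_life", cfg.costs.end_of_life
    yield "costs.best_supportive_care_per_cycle", cfg.costs.best_supportive_care_per_cycle
    for name, d in cfg.drugs.items():
        yield f"drugs.{name}.unit_cost", d.unit_cost
    for arm, p in cfg.subsequent_treatment.rate.items():
        yield f"subsequent.{arm}", p
    for name, p in cfg.adverse_events.costs.items():
        yield f"ae.costs.{name}", p
    for name, p in cfg.adverse_events.disutilities.items():
        yield f"ae.disutilities.{name}", p
    for arm, block in cfg.adverse_events.incidence.items():
        for name, p in block.items():
            yield f"ae.incidence.{arm}.{name}", p


def parameter_specs(cfg: ModelConfig) -> list[ParamDistribution]:
    """The uncertain-parameter registry driving the DSA and PSA.

    Parameters marked ``fixed`` are excluded from the PSA but still varied in
    the DSA over their printed ranges; parameters with no range take part in
    neither.
    """
    specs = []
    for name, p in _walk_params(cfg):
        has_range = p.low is not None
        specs.append(
            ParamDistribution(
                name=name,
                base=p.base,
                low=p.low,
                high=p.high,
                family=p.dist,
                in_psa=p.dist != "fixed",
                in_dsa=has_range,
            )
        )
    return specs


def resolve_inputs(cfg: ModelConfig, overrides: dict[str, float] | None = None) -> ModelInputs:
    """Flatten a configuration (plus overrides) into :class:`ModelInputs`."""
    overrides = dict(overrides or {})
    used = set()

    def val(name: str, param: Param) -> float:
        if name in overrides:
            used.add(name)
            return float(overrides[name])
        return param.base

    engine = EngineConfig(
        cycle_length_days=cfg.engine.cycle_length_days,
        horizon_years=cfg.engine.horizon_years,
        discount_rate=val("engine.discount_rate", cfg.engine.discount_rate),
    )
    profile = PatientProfile(
        weight_kg=val("patient.weight_kg", cfg.patient.weight_kg),
        bsa_m2=val("patient.bsa_m2", cfg.patient.bsa_m2),
    )

    def spec_for(name: str, d: DrugConfig, first_line: bool) -> DrugSpec:
        return DrugSpec(
            name=name,
            unit_size_mg=d.unit_size_mg,
            unit_cost=val(f"drugs.{name}.unit_cost", d.unit_cost),
            dose_rule=d.dose_rule,
            dose_amount=d.dose_amount,
            admins_per_cycle=d.admins_per_cycle,
            loading_per_kg=d.loading_per_kg,
            cap_cycles=cfg.first_line.cap_cycles if first_line else None,
            cycle_days=d.cycle_days,
        )

    first_line: dict[str, tuple] = {}
    for arm in ARMS:
        drugs = []
        for name, d in cfg.drugs.items():
            if d.line != "first":
                continue
            if d.arms is not None and arm not in d.arms:
                continue
            if d.component == "backbone":
                weight = 1.0
            else:
                weight = cfg.first_line.chemo_mix[arm][d.component]
            drugs.append((weight, spec_for(name, d, first_line=True)))
        first_line[arm] = tuple(drugs)

    second_line = tuple(
        spec_for(name, d, first_line=False)
        for name, d in cfg.drugs.items()
        if d.line == "second"
    )

    aes: dict[str, tuple] = {}
    for arm, block in cfg.adverse_events.incidence.items():
        aes[arm] = tuple(
            AdverseEvent(
                name=name,
                incidence=val(f"ae.incidence.{arm}.{name}", p),
                cost=val(f"ae.costs.{name}", cfg.adverse_events.costs[name]),
                disutility=val(
                    f"ae.disutilities.{name}", cfg.adverse_events.disutilities[name]
                ),
            )
            for name, p in block.items()
        )

    mi = ModelInputs(
        engine=engine,
        profile=profile,
        u_pfs=val("utilities.pfs", cfg.utilities.pfs),
        u_pd=val("utilities.pd", cfg.utilities.pd),
        follow_up_per_cycle=val("costs.follow_up_per_cycle", cfg.costs.follow_up_per_cycle),
        administration_per_cycle=val(
            "costs.administration_per_cycle", cfg.costs.administration_per_cycle
        ),
        end_of_life=val("costs.end_of_life", cfg.costs.end_of_life),
        bsc_per_cycle=val(
            "costs.best_supportive_care_per_cycle", cfg.costs.best_supportive_care_per_cycle
        ),
        first_line=first_line,
        second_line=second_line,
        cap_cycles=cfg.first_line.cap_cycles,
        subsequent_rate={
            arm: val(f"subsequent.{arm}", p)
            for arm, p in cfg.subsequent_treatment.rate.items()
        },
        adverse_events=aes,
        wtp=cfg.wtp,
        assistance_mode=cfg.assistance.mode,
        assistance_free_after=cfg.assistance.free_after_n,
        pd_bsc_additive=cfg.pd_costing.bsc_additive,
    )
    unknown = set(overrides) - used
    if unknown:
        raise KeyError(f"unknown parameter overrides: {sorted(unknown)}")
    return mi
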