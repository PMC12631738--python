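"""Costs and QALYs accrued over a state trace.

Costing follows the treatment pathway of first-line HER2-positive gastric /
GEJ adenocarcinoma therapy: while progression-free, patients receive the
arm's first-line regimen (pembrolizumab where applicable, trastuzumab with a
first-cycle loading dose, and a regimen-mix-weighted fluoropyrimidine–
platinum backbone) plus an administration fee, for at most ``cap_cycles``
cycles; routine follow-up continues for life.  After progression, a fixed
proportion of each arm receives second-line ramucirumab + paclitaxel (priced
per 28-day cycle and pro-rated onto the model cycle) while the remainder
receives best supportive care.  Grade >= 3 adverse events are applied once,
in the first cycle, as a one-off cost and QALY loss.  A one-time end-of-life
cost attaches to the incident-death mass each cycle.

Drug pricing is linear in the dose (no vial rounding) by default:
``cost = dose_mg / unit_size_mg * unit_cost`` summed over the administrations
scheduled in a cycle; ceiling-to-vial wastage is available as a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .engine import EngineConfig, StateTrace, life_years

__all__ = [
    "ARMS",
    "PatientProfile",
    "DrugSpec",
    "AdverseEvent",
    "ModelInputs",
    "ArmResult",
    "drug_cost_per_cycle",
    "first_line_cycle_cost",
    "first_line_cost_vector",
    "second_line_cycle_cost",
    "pd_cycle_cost",
    "ae_one_off",
    "accumulate",
]

ARMS = ("PEM", "TRAS")

DOSE_RULES = ("flat_mg", "per_kg", "per_m2")


@dataclass(frozen=True)
class PatientProfile:
    """Reference body metrics used for weight- and BSA-based dosing."""

    weight_kg: float = 60.0
    bsa_m2: float = 1.6

    def __post_init__(self):
        if self.weight_kg <= 0 or self.bsa_m2 <= 0:
            raise ValueError("body metrics must be positive")


@dataclass(frozen=True)
class DrugSpec:
    """Dosing and pricing rule for one drug.

    ``dose_amount`` is mg (flat_mg), mg/kg (per_kg) or mg/m2 (per_m2) per
    administration; ``admins_per_cycle`` administrations are given per
    ``cycle_days``-day cycle.  ``loading_per_kg`` overrides the per-kg dose at
    cycle 0.  ``cap_cycles`` zeroes the cost from that cycle index on.
    """

    name: str
    unit_size_mg: float
    unit_cost: float
    dose_rule: str
    dose_amount: float
    admins_per_cycle: int = 1
    loading_per_kg: float | None = None
    cap_cycles: int | None = None
    cycle_days: float = 21.0
    vial_rounding: bool = False

    def __post_init__(self):
        if self.dose_rule not in DOSE_RULES:
            raise ValueError(f"dose_rule must be one of {DOSE_RULES}")
        if self.unit_size_mg <= 0:
            raise ValueError("unit_size_mg must be positive")
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be non-negative")
        if self.dose_amount < 0:
            raise ValueError("dose_amount must be non-negative")


@dataclass(frozen=True)
class AdverseEvent:
    """One grade >= 3 adverse event: incidence, management cost, disutility."""

    name: str
    incidence: float
    cost: float
    disutility: float

    def __post_init__(self):
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"AE incidence must be in [0, 1], got {self.incidence}")
        if self.cost < 0 or self.disutility < 0:
            raise ValueError("AE cost and disutility must be non-negative")


@dataclass(frozen=True)
class ModelInputs:
    """Fully resolved numeric inputs for one model run (both arms)."""

    engine: EngineConfig
    profile: PatientProfile
    u_pfs: float
    u_pd: float
    follow_up_per_cycle: float
    administration_per_cycle: float
    end_of_life: float
    bsc_per_cycle: float
    # first-line drugs per arm as (mix weight, spec); weight 1 for backbone
    first_line: dict[str, tuple[tuple[float, DrugSpec], ...]]
    second_line: tuple[DrugSpec, ...]
    cap_cycles: int
    subsequent_rate: dict[str, float]
    adverse_events: dict[str, tuple[AdverseEvent, ...]]
    wtp: float
    # pembrolizumab assistance: "off", or "free_after_n" (first
    # `assistance_free_after` cycles self-paid, later cycles program-funded)
    assistance_mode: str = "off"
    assistance_free_after: int = 4
    # PD costing: BSC as alternative to (False) or on top of (True) treatment
    pd_bsc_additive: bool = False
    # AE disutility duration: one model cycle ("cycle") or an absolute
    # one-year-equivalent decrement ("absolute")
    ae_disutility_mode: str = "cycle"

    def __post_init__(self):
        for u in (self.u_pfs, self.u_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utilities must be in [0, 1], got {u}")
        for arm, r in self.subsequent_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"subsequent-treatment rate for {arm} out of [0, 1]")
        # regimen-mix weights summing to 1 per arm is enforced at the
        # configuration layer, where the regimen structure is still visible
        if self.assistance_mode not in ("off", "free_after_n"):
            raise ValueError("assistance_mode must be 'off' or 'free_after_n'")
        if self.ae_disutility_mode not in ("cycle", "absolute"):
            raise ValueError("ae_disutility_mode must be 'cycle' or 'absolute'")


def dose_mg(spec: DrugSpec, profile: PatientProfile, loading: bool = False) -> float:
    """Dose in mg for a single administration."""
    if loading and spec.loading_per_kg is not None:
        return spec.loading_per_kg * profile.weight_kg
    if spec.dose_rule == "flat_mg":
        return spec.dose_amount
    if spec.dose_rule == "per_kg":
        return spec.dose_amount * profile.weight_kg
    return spec.dose_amount * profile.bsa_m2


def drug_cost_per_cycle(spec: DrugSpec, profile: PatientProfile, cycle_index: int) -> float:
    """Cost of one cycle of one drug at the given cycle index."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    if spec.cap_cycles is not None and cycle_index >= spec.cap_cycles:
        return 0.0
    dose = dose_mg(spec, profile, loading=cycle_index == 0)
    if dose < 0:
        raise ValueError("negative dose")
    units = dose / spec.unit_size_mg
    if spec.vial_rounding:
        units = math.ceil(units)
    return units * spec.unit_cost * spec.admins_per_cycle


def _assistance_paid(mi: ModelInputs, cycle_index) -> np.ndarray:
    """1.0 where a pembrolizumab cycle is self-paid, 0.0 where program-funded.

    Under ``free_after_n`` the first ``assistance_free_after`` cycles are
    self-paid and every later cycle of the treatment course is supplied by
    the assistance program.
    """
    idx = np.asarray(cycle_index)
    if mi.assistance_mode == "off":
        return np.ones_like(idx, dtype=float)
    return (idx < mi.assistance_free_after).astype(float)


def first_line_cycle_cost(arm: str, mi: ModelInputs, cycle_index: int) -> float:
    """All-in first-line cost of one PFS cycle: drugs + administration +
    follow-up, respecting the treatment cap."""
    if arm not in mi.first_line:
        raise ValueError(f"unknown arm {arm!r}")
    total = mi.follow_up_per_cycle
    if cycle_index >= mi.cap_cycles:
        return total  # treatment ceased; only follow-up continues
    total += mi.administration_per_cycle
    for weight, spec in mi.first_line[arm]:
        c = drug_cost_per_cycle(spec, mi.profile, cycle_index)
        if spec.name == "pembrolizumab":
            c *= float(_assistance_paid(mi, cycle_index))
        total += weight * c
    return total


def first_line_cost_vector(arm: str, mi: ModelInputs, n_cycles: int) -> np.ndarray:
    """Vector of first-line cycle costs for cycles 0..n_cycles-1."""
    if arm not in mi.first_line:
        raise ValueError(f"unknown arm {arm!r}")
    idx = np.arange(n_cycles)
    on_treat = (idx < mi.cap_cycles).astype(float)
    cost = np.full(n_cycles, mi.follow_up_per_cycle)
    cost += on_treat * mi.administration_per_cycle
    for weight, spec in mi.first_line[arm]:
        steady = drug_cost_per_cycle(spec, mi.profile, cycle_index=1)
        v = np.full(n_cycles, steady)
        v[0] = drug_cost_per_cycle(spec, mi.profile, cycle_index=0)
        if spec.name == "pembrolizumab":
            v *= _assistance_paid(mi, idx)
        cost += weight * v * on_treat
    return cost


def second_line_cycle_cost(mi: ModelInputs) -> float:
    """Second-line drug cost pro-rated from its own cycle onto the model cycle."""
    total = 0.0
    for spec in mi.second_line:
        per_own_cycle = drug_cost_per_cycle(replace(spec, loading_per_kg=None), mi.profile, 1)
        total += per_own_cycle * mi.engine.cycle_length_days / spec.cycle_days
    return total


def pd_cycle_cost(arm: str, mi: ModelInputs) -> float:
    """Cost of one model cycle in the progressed-disease state."""
    rate = mi.subsequent_rate[arm]
    treated = second_line_cycle_cost(mi) + mi.administration_per_cycle
    if mi.pd_bsc_additive:
        return rate * treated + mi.bsc_per_cycle + mi.follow_up_per_cycle
    return rate * treated + (1.0 - rate) * mi.bsc_per_cycle + mi.follow_up_per_cycle


def ae_one_off(aes, duration_years: float) -> tuple[float, float]:
    """One-off adverse-event burden: (expected cost, expected QALY loss).

    Each event contributes incidence * cost and incidence * disutility *
    duration_years, applied once at the start of treatment.
    """
    cost = sum(ae.incidence * ae.cost for ae in aes)
    qaly_loss = sum(ae.incidence * ae.disutility * duration_years for ae in aes)
    return float(cost), float(qaly_loss)


@dataclass(frozen=True)
class ArmResult:
    """Discounted, state-split costs, QALYs and LYs for one strategy.

    ``qaly_pfs`` already carries the one-off adverse-event QALY loss; totals
    are exact component sums.
    """

    arm: str
    cost_pfs: float
    cost_pd: float
    cost_death: float
    qaly_pfs: float
    qaly_pd: float
    ly_pfs: float
    ly_pd: float

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_pd + self.cost_death

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_pd

    @property
    def ly_total(self) -> float:
        return self.ly_pfs + self.ly_pd


def accumulate(trace: StateTrace, arm: str, mi: ModelInputs) -> ArmResult:
    """Run the costing and utility weighting over a state trace."""
    if abs(trace.config.cycle_length_days - mi.engine.cycle_length_days) > 1e-9:
        raise ValueError("trace and inputs use different cycle lengths")
    cy = trace.config.cycle_years
    flc = first_line_cost_vector(arm, mi, trace.n_cycles)
    pdc = pd_cycle_cost(arm, mi)

    ae_duration = cy if mi.ae_disutility_mode == "cycle" else 1.0
    ae_cost, ae_loss = ae_one_off(mi.adverse_events.get(arm, ()), ae_duration)

    df0 = float(trace.df[0])
    cost_pfs = float(np.sum(trace.occ_pfs * flc * trace.df)) + ae_cost * df0
    cost_pd = float(np.sum(trace.occ_pd * pdc * trace.df))
    cost_death = float(np.sum(trace.incident_deaths * mi.end_of_life * trace.df))
    qaly_pfs = float(np.sum(trace.occ_pfs * mi.u_pfs * cy * trace.df)) - ae_loss * df0
    qaly_pd = float(np.sum(trace.occ_pd * mi.u_pd * cy * trace.df))
    ly_pfs, ly_pd, _ = life_years(trace, discounted=True)
    return ArmResult(arm, cost_pfs, cost_pd, cost_death, qaly_pfs, qaly_pd, ly_pfs, ly_pd)
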