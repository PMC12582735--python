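"""Per-cycle drug, adverse-event, and healthcare-service cost accrual.

Costing follows the payer perspective in Jordanian dinar (JOD).  Drug cost
is dose-linear (per-mg unit prices times daily dose times 90 days per
trimester), with a titration dose in cycle 1 and a maintenance dose
afterwards; the wastage assumption means dose reductions earn no cost
credit, so no reduction pathway is modelled.  Each health state carries a
fixed service bundle per cycle (outpatient visits, EEG, emergency and
inpatient care).  Adverse events occur with annual probabilities converted
to per-cycle probabilities, trigger a GP visit, and — for ataxia,
dizziness and nausea — a management drug course.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .econ import DiscountSpec, discount_factor
from .errors import ConfigurationError, ModelValidationError
from .model import CohortTrace, HealthState

__all__ = [
    "DoseSchedule",
    "UnitCosts",
    "AEProfile",
    "AEManagement",
    "ServiceBundle",
    "ResourceUseRules",
    "CostModel",
    "drug_cost_per_cycle",
    "ae_cycle_probability",
    "state_cost_per_cycle",
    "ae_expected_cost_per_cycle",
    "total_expected_cost",
    "cost_breakdown",
    "default_resource_rules",
]

ADVERSE_EVENTS = ("ataxia", "dizziness", "fatigue", "nausea", "somnolence")
CYCLES_PER_YEAR = 4


@dataclass(frozen=True)
class DoseSchedule:
    """Daily dose in mg: titration during cycle 1, maintenance afterwards."""

    treatment: str
    titration_daily_dose_mg: float
    maintenance_daily_dose_mg: float

    def __post_init__(self) -> None:
        if self.titration_daily_dose_mg <= 0 or self.maintenance_daily_dose_mg <= 0:
            raise ModelValidationError(
                f"{self.treatment}: daily doses must be positive"
            )

    def daily_dose(self, cycle_index: int) -> float:
        if cycle_index < 1:
            raise ConfigurationError(f"cycle_index must be >= 1, got {cycle_index}")
        return (
            self.titration_daily_dose_mg
            if cycle_index == 1
            else self.maintenance_daily_dose_mg
        )


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in JOD; per-mg prices for drugs, per-event for services."""

    drug_cost_per_mg: dict[str, float]
    ae_drug_cost_per_mg: dict[str, float] = field(
        default_factory=lambda: {"acetazolamide": 0.001, "cinnarizine": 0.001}
    )
    inpatient_night: float = 100.0
    emergency_visit: float = 30.0
    neurologist_visit: float = 14.0
    gp_visit: float = 8.0
    eeg: float = 100.0
    cost_variation: float = 0.25

    def __post_init__(self) -> None:
        services = (
            self.inpatient_night,
            self.emergency_visit,
            self.neurologist_visit,
            self.gp_visit,
            self.eeg,
        )
        if any(c < 0 for c in services):
            raise ModelValidationError("service unit costs must be >= 0")
        if any(c < 0 for c in self.drug_cost_per_mg.values()):
            raise ModelValidationError("drug per-mg costs must be >= 0")
        if any(c < 0 for c in self.ae_drug_cost_per_mg.values()):
            raise ModelValidationError("AE drug per-mg costs must be >= 0")

    def scaled(self, factor: float) -> "UnitCosts":
        """All unit costs multiplied by ``factor`` (homogeneity helper)."""
        return replace(
            self,
            drug_cost_per_mg={k: v * factor for k, v in self.drug_cost_per_mg.items()},
            ae_drug_cost_per_mg={
                k: v * factor for k, v in self.ae_drug_cost_per_mg.items()
            },
            inpatient_night=self.inpatient_night * factor,
            emergency_visit=self.emergency_visit * factor,
            neurologist_visit=self.neurologist_visit * factor,
            gp_visit=self.gp_visit * factor,
            eeg=self.eeg * factor,
        )


@dataclass(frozen=True)
class AEProfile:
    """Annual probabilities of the five modelled adverse events."""

    treatment: str
    ataxia: float
    dizziness: float
    fatigue: float
    nausea: float
    somnolence: float

    def __post_init__(self) -> None:
        for name in ADVERSE_EVENTS:
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ModelValidationError(
                    f"{self.treatment}: annual probability of {name} must be in [0, 1]"
                )

    def annual_probability(self, event: str) -> float:
        if event not in ADVERSE_EVENTS:
            raise ModelValidationError(f"unknown adverse event {event!r}")
        return getattr(self, event)


@dataclass(frozen=True)
class AEManagement:
    """Management rule for one adverse event.

    ``drug`` is None when the event gets no pharmacological intervention
    (fatigue, somnolence); every event still triggers ``gp_visits`` GP
    visits.  Default course is the full 90-day cycle, consistent with the
    conservative wastage assumption.
    """

    drug: str | None = None
    daily_dose_mg: float = 0.0
    treated_days: int = 90
    gp_visits: int = 1


@dataclass(frozen=True)
class ServiceBundle:
    """Per-cycle healthcare service counts for one health state."""

    neurologist_visits: float = 0.0
    gp_visits: float = 0.0
    eeg_tests: float = 0.0
    emergency_visits: float = 0.0
    inpatient_nights: float = 0.0

    def cost(self, unit: UnitCosts) -> float:
        return (
            self.neurologist_visits * unit.neurologist_visit
            + self.gp_visits * unit.gp_visit
            + self.eeg_tests * unit.eeg
            + self.emergency_visits * unit.emergency_visit
            + self.inpatient_nights * unit.inpatient_night
        )


@dataclass(frozen=True)
class ResourceUseRules:
    """State -> service bundle and adverse event -> management mappings."""

    state_bundles: dict[HealthState, ServiceBundle]
    ae_management: dict[str, AEManagement]

    def __post_init__(self) -> None:
        missing = [s.name for s in HealthState if s not in self.state_bundles]
        if missing:
            raise ModelValidationError(f"no service bundle for states: {missing}")
        missing = [e for e in ADVERSE_EVENTS if e not in self.ae_management]
        if missing:
            raise ModelValidationError(f"no management rule for adverse events: {missing}")


def default_resource_rules(
    acetazolamide_daily_mg: float = 500.0,
    cinnarizine_daily_mg: float = 75.0,
    treated_days: int = 90,
    nonresponse_outpatient_visits: float = 1.0,
) -> ResourceUseRules:
    """Resource-use assumptions: follow-up bundles per state, AE management.

    Seizure-free and partial responders get one neurologist visit and an
    EEG per trimester; non-responders additionally an emergency admission
    and one inpatient night; discontinued patients only an outpatient
    visit.  Ataxia is managed with acetazolamide, dizziness and nausea with
    cinnarizine, fatigue and somnolence with no drug; every event adds one
    GP visit.
    """
    followup = ServiceBundle(neurologist_visits=1.0, eeg_tests=1.0)
    return ResourceUseRules(
        state_bundles={
            HealthState.SEIZURE_FREE: followup,
            HealthState.PARTIAL_RESPONSE: followup,
            HealthState.NON_RESPONSE: ServiceBundle(
                neurologist_visits=nonresponse_outpatient_visits,
                eeg_tests=1.0,
                emergency_visits=1.0,
                inpatient_nights=1.0,
            ),
            HealthState.DISCONTINUED: ServiceBundle(neurologist_visits=1.0),
        },
        ae_management={
            "ataxia": AEManagement("acetazolamide", acetazolamide_daily_mg, treated_days),
            "dizziness": AEManagement("cinnarizine", cinnarizine_daily_mg, treated_days),
            "nausea": AEManagement("cinnarizine", cinnarizine_daily_mg, treated_days),
            "fatigue": AEManagement(None),
            "somnolence": AEManagement(None),
        },
    )


def drug_cost_per_cycle(
    schedule: DoseSchedule,
    unit: UnitCosts,
    cycle_index: int,
    cycle_length_days: int = 90,
) -> float:
    """Antiseizure drug cost of one fully adherent patient for one cycle."""
    cost_per_mg = unit.drug_cost_per_mg.get(schedule.treatment)
    if cost_per_mg is None:
        raise ModelValidationError(f"no per-mg cost for treatment {schedule.treatment!r}")
    return schedule.daily_dose(cycle_index) * cycle_length_days * cost_per_mg


def ae_cycle_probability(annual_p: float, cycles_per_year: int = CYCLES_PER_YEAR) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Assumes a constant hazard within the year: 1 - (1 - p)^(1/cycles).
    """
    if not 0.0 <= annual_p <= 1.0:
        raise ModelValidationError(f"annual probability must be in [0, 1], got {annual_p}")
    return float(1.0 - (1.0 - annual_p) ** (1.0 / cycles_per_year))


def state_cost_per_cycle(
    state: HealthState, rules: ResourceUseRules, unit: UnitCosts
) -> float:
    """Healthcare-service cost of occupying ``state`` for one cycle."""
    try:
        bundle = rules.state_bundles[HealthState(state)]
    except (KeyError, ValueError) as exc:
        raise ModelValidationError(f"no service bundle for state {state!r}") from exc
    return bundle.cost(unit)


def ae_expected_cost_per_cycle(
    ae: AEProfile, rules: ResourceUseRules, unit: UnitCosts
) -> float:
    """Expected per-patient adverse-event cost for one cycle on treatment."""
    total = 0.0
    for event in ADVERSE_EVENTS:
        try:
            mgmt = rules.ae_management[event]
        except KeyError as exc:
            raise ModelValidationError(f"no management rule for {event!r}") from exc
        p_cycle = ae_cycle_probability(ae.annual_probability(event))
        event_cost = mgmt.gp_visits * unit.gp_visit
        if mgmt.drug is not None:
            try:
                per_mg = unit.ae_drug_cost_per_mg[mgmt.drug]
            except KeyError as exc:
                raise ModelValidationError(
                    f"no per-mg cost for AE management drug {mgmt.drug!r}"
                ) from exc
            event_cost += mgmt.daily_dose_mg * mgmt.treated_days * per_mg
        total += p_cycle * event_cost
    return total


@dataclass(frozen=True)
class CostModel:
    """Everything needed to cost a cohort trace for one treatment."""

    schedule: DoseSchedule
    unit_costs: UnitCosts
    ae_profile: AEProfile
    rules: ResourceUseRules
    #: "all_cycles" accrues AE cost every cycle for the persisting cohort;
    #: "first_year" restricts accrual to cycles 1-4.
    ae_accrual: str = "all_cycles"

    def __post_init__(self) -> None:
        if self.ae_accrual not in ("all_cycles", "first_year"):
            raise ConfigurationError(f"unknown ae_accrual {self.ae_accrual!r}")


def cost_breakdown(
    trace: CohortTrace,
    cost_model: CostModel,
    discount: DiscountSpec,
    cycle_length_days: int = 90,
):
    """Per-cycle cost components for one treatment.

    Returns a DataFrame with columns cycle, component (drug | services |
    ae), undiscounted, discounted.  Discontinued patients accrue neither
    drug nor adverse-event cost, only their (outpatient) service bundle.
    """
    import pandas as pd

    n = trace.n_cycles
    state_costs = np.array(
        [
            state_cost_per_cycle(state, cost_model.rules, cost_model.unit_costs)
            for state in HealthState
        ]
    )
    ae_cost = ae_expected_cost_per_cycle(
        cost_model.ae_profile, cost_model.rules, cost_model.unit_costs
    )
    rows = []
    for cycle in range(1, n + 1):
        occ = trace.occupancy[cycle - 1]
        on_treatment = 1.0 - occ[HealthState.DISCONTINUED]
        factor = discount_factor(cycle, discount, n_cycles=n)
        drug = on_treatment * drug_cost_per_cycle(
            cost_model.schedule, cost_model.unit_costs, cycle, cycle_length_days
        )
        services = float(occ @ state_costs)
        accrue_ae = cost_model.ae_accrual == "all_cycles" or cycle <= CYCLES_PER_YEAR
        ae = on_treatment * ae_cost if accrue_ae else 0.0
        for component, value in (("drug", drug), ("services", services), ("ae", ae)):
            rows.append(
                {
                    "cycle": cycle,
                    "component": component,
                    "undiscounted": value,
                    "discounted": value * factor,
                }
            )
    return pd.DataFrame(rows)


def total_expected_cost(
    trace: CohortTrace,
    cost_model: CostModel,
    discount: DiscountSpec,
    cycle_length_days: int = 90,
) -> float:
    """Total discounted expected cost per patient over the horizon, in JOD."""
    n = trace.n_cycles
    occ = trace.occupancy
    state_costs = np.array(
        [
            state_cost_per_cycle(state, cost_model.rules, cost_model.unit_costs)
            for state in HealthState
        ]
    )
    ae_cost = ae_expected_cost_per_cycle(
        cost_model.ae_profile, cost_model.rules, cost_model.unit_costs
    )
    on_treatment = 1.0 - occ[:, HealthState.DISCONTINUED]
    cycles = np.arange(1, n + 1)
    factors = np.array([discount_factor(c, discount, n_cycles=n) for c in cycles])
    drug = np.array(
        [
            drug_cost_per_cycle(
                cost_model.schedule, cost_model.unit_costs, c, cycle_length_days
            )
            for c in cycles
        ]
    )
    accrue_ae = (
        np.ones(n, bool)
        if cost_model.ae_accrual == "all_cycles"
        else cycles <= CYCLES_PER_YEAR
    )
    per_cycle = (
        on_treatment * drug
        + occ @ state_costs
        + np.where(accrue_ae, on_treatment * ae_cost, 0.0)
    )
    return float(np.sum(factors * per_cycle))
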