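"""Schema-validated model configuration and YAML I/O.

A :class:`ModelConfig` carries everything one run needs: per-treatment
transition profiles with standard errors, adverse-event probabilities,
dose schedules and per-mg prices; healthcare-service unit costs;
adverse-event management rules; cycle structure; discounting; PSA
settings; and the willingness-to-pay grid.  The packaged default
configuration (``cohortcea/data/default.yaml``) ships the published
Jordanian inputs; the dose schedule entries there are label-based
assumptions and are marked as such in the file.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .costing import (
    ADVERSE_EVENTS,
    AEManagement,
    AEProfile,
    CostModel,
    DoseSchedule,
    ResourceUseRules,
    ServiceBundle,
    UnitCosts,
)
from .econ import DiscountSpec
from .errors import ModelValidationError
from .model import (
    EffectDefinition,
    HealthState,
    ModelSpec,
    StructuralVariant,
    TransitionProfile,
)
from .psa import PSAConfig

__all__ = ["ModelConfig", "load_config", "save_config", "default_config"]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TransitionsConfig(_Base):
    p_sf: float
    p_pr: float
    p_nr: float
    p_disc: float
    se_sf: float = 0.0
    se_pr: float = 0.0
    se_nr: float = 0.0
    se_disc: float = 0.0


class DoseConfig(_Base):
    titration_daily_dose_mg: float = Field(gt=0)
    maintenance_daily_dose_mg: float = Field(gt=0)


class TreatmentConfig(_Base):
    transitions: TransitionsConfig
    ae_annual_probabilities: dict[str, float]
    dose: DoseConfig
    drug_cost_per_mg: float = Field(ge=0)
    drug_cost_se: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check_ae_events(self):
        missing = sorted(set(ADVERSE_EVENTS) - set(self.ae_annual_probabilities))
        if missing:
            raise ValueError(f"ae_annual_probabilities missing events: {missing}")
        return self


class ServicesConfig(_Base):
    inpatient_night: float = Field(default=100.0, ge=0)
    emergency_visit: float = Field(default=30.0, ge=0)
    neurologist_visit: float = Field(default=14.0, ge=0)
    gp_visit: float = Field(default=8.0, ge=0)
    eeg: float = Field(default=100.0, ge=0)
    cost_variation: float = Field(default=0.25, ge=0)


class AEDrugCostConfig(_Base):
    cost_per_mg: float = Field(ge=0)
    cost_se: float = Field(default=0.0, ge=0)


class AEManagementConfig(_Base):
    drug: str | None = None
    daily_dose_mg: float = Field(default=0.0, ge=0)
    treated_days: int = Field(default=90, ge=0)
    gp_visits: int = Field(default=1, ge=0)


class BundleConfig(_Base):
    neurologist_visits: float = Field(default=0.0, ge=0)
    gp_visits: float = Field(default=0.0, ge=0)
    eeg_tests: float = Field(default=0.0, ge=0)
    emergency_visits: float = Field(default=0.0, ge=0)
    inpatient_nights: float = Field(default=0.0, ge=0)


class ModelSettingsConfig(_Base):
    cycle_length_days: int = Field(default=90, gt=0)
    n_cycles: int = Field(default=8, ge=1)
    structural_variant: StructuralVariant = StructuralVariant.ABSORBING_SF_DISC
    effect_definition: EffectDefinition = EffectDefinition.EVER_SF


class DiscountConfig(_Base):
    annual_rate: float = Field(default=0.035, ge=0)
    psa_low: float = Field(default=0.0, ge=0)
    psa_high: float = Field(default=0.05, ge=0)


class PSASettingsConfig(_Base):
    n_iterations: int = Field(default=2000, ge=1)
    seed: int = 0
    ae_probability_pct: float = Field(default=0.25, ge=0)
    discount_rate_se: float = Field(default=0.00625, ge=0)


class ModelConfig(_Base):
    """Fully validated configuration for one cost-effectiveness analysis."""

    treatments: dict[str, TreatmentConfig]
    reference: str = "BRV"
    services: ServicesConfig = ServicesConfig()
    ae_drug_costs: dict[str, AEDrugCostConfig] = Field(
        default_factory=lambda: {
            "acetazolamide": AEDrugCostConfig(cost_per_mg=0.001, cost_se=0.001),
            "cinnarizine": AEDrugCostConfig(cost_per_mg=0.001, cost_se=0.001),
        }
    )
    ae_management: dict[str, AEManagementConfig] = Field(
        default_factory=lambda: {
            "ataxia": AEManagementConfig(drug="acetazolamide", daily_dose_mg=500.0),
            "dizziness": AEManagementConfig(drug="cinnarizine", daily_dose_mg=75.0),
            "nausea": AEManagementConfig(drug="cinnarizine", daily_dose_mg=75.0),
            "fatigue": AEManagementConfig(),
            "somnolence": AEManagementConfig(),
        }
    )
    state_bundles: dict[str, BundleConfig] = Field(
        default_factory=lambda: {
            "SEIZURE_FREE": BundleConfig(neurologist_visits=1, eeg_tests=1),
            "PARTIAL_RESPONSE": BundleConfig(neurologist_visits=1, eeg_tests=1),
            "NON_RESPONSE": BundleConfig(
                neurologist_visits=1, eeg_tests=1, emergency_visits=1, inpatient_nights=1
            ),
            "DISCONTINUED": BundleConfig(neurologist_visits=1),
        }
    )
    model: ModelSettingsConfig = ModelSettingsConfig()
    discount: DiscountConfig = DiscountConfig()
    psa: PSASettingsConfig = PSASettingsConfig()
    ae_accrual: Literal["all_cycles", "first_year"] = "all_cycles"
    wtp_threshold: float = Field(default=9000.0, ge=0)
    wtp_grid_max: float = Field(default=12000.0, gt=0)
    wtp_grid_step: float = Field(default=500.0, gt=0)

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.reference not in self.treatments:
            raise ValueError(
                f"reference treatment {self.reference!r} not among treatments "
                f"{sorted(self.treatments)}"
            )
        for name in HealthState:
            if name.name not in self.state_bundles:
                raise ValueError(f"state_bundles missing state {name.name}")
        missing = sorted(set(ADVERSE_EVENTS) - set(self.ae_management))
        if missing:
            raise ValueError(f"ae_management missing events: {missing}")
        for event, rule in self.ae_management.items():
            if rule.drug is not None and rule.drug not in self.ae_drug_costs:
                raise ValueError(
                    f"ae_management[{event}] references drug {rule.drug!r} "
                    "with no entry in ae_drug_costs"
                )
        # trigger simplex/SE validation with treatment-specific messages
        for name in self.treatments:
            self.transition_profile(name)
        return self

    # ---- conversion to domain objects -------------------------------------

    def transition_profile(self, treatment: str) -> TransitionProfile:
        t = self.treatments[treatment].transitions
        return TransitionProfile(
            treatment=treatment,
            p_sf=t.p_sf, p_pr=t.p_pr, p_nr=t.p_nr, p_disc=t.p_disc,
            se_sf=t.se_sf, se_pr=t.se_pr, se_nr=t.se_nr, se_disc=t.se_disc,
        )

    def transition_profiles(self) -> dict[str, TransitionProfile]:
        return {name: self.transition_profile(name) for name in self.treatments}

    def model_spec(self) -> ModelSpec:
        m = self.model
        return ModelSpec(
            cycle_length_days=m.cycle_length_days,
            n_cycles=m.n_cycles,
            structural_variant=m.structural_variant,
            effect_definition=m.effect_definition,
        )

    def discount_spec(self) -> DiscountSpec:
        d = self.discount
        return DiscountSpec(annual_rate=d.annual_rate, psa_range=(d.psa_low, d.psa_high))

    def unit_costs(self) -> UnitCosts:
        return UnitCosts(
            drug_cost_per_mg={
                name: t.drug_cost_per_mg for name, t in self.treatments.items()
            },
            ae_drug_cost_per_mg={
                name: c.cost_per_mg for name, c in self.ae_drug_costs.items()
            },
            inpatient_night=self.services.inpatient_night,
            emergency_visit=self.services.emergency_visit,
            neurologist_visit=self.services.neurologist_visit,
            gp_visit=self.services.gp_visit,
            eeg=self.services.eeg,
            cost_variation=self.services.cost_variation,
        )

    def resource_rules(self) -> ResourceUseRules:
        return ResourceUseRules(
            state_bundles={
                HealthState[name]: ServiceBundle(**bundle.model_dump())
                for name, bundle in self.state_bundles.items()
            },
            ae_management={
                event: AEManagement(**rule.model_dump())
                for event, rule in self.ae_management.items()
            },
        )

    def ae_profile(self, treatment: str) -> AEProfile:
        probs = self.treatments[treatment].ae_annual_probabilities
        return AEProfile(
            treatment=treatment, **{e: probs[e] for e in ADVERSE_EVENTS}
        )

    def dose_schedule(self, treatment: str) -> DoseSchedule:
        d = self.treatments[treatment].dose
        return DoseSchedule(
            treatment=treatment,
            titration_daily_dose_mg=d.titration_daily_dose_mg,
            maintenance_daily_dose_mg=d.maintenance_daily_dose_mg,
        )

    def cost_model(self, treatment: str) -> CostModel:
        return CostModel(
            schedule=self.dose_schedule(treatment),
            unit_costs=self.unit_costs(),
            ae_profile=self.ae_profile(treatment),
            rules=self.resource_rules(),
            ae_accrual=self.ae_accrual,
        )

    def cost_models(self) -> dict[str, CostModel]:
        return {name: self.cost_model(name) for name in self.treatments}

    def psa_config(self, seed: int | None = None, n_iterations: int | None = None) -> PSAConfig:
        p = self.psa
        return PSAConfig(
            n_iterations=n_iterations if n_iterations is not None else p.n_iterations,
            seed=seed if seed is not None else p.seed,
            reference=self.reference,
            ae_probability_pct=p.ae_probability_pct,
            discount_rate_se=p.discount_rate_se,
        )

    def drug_cost_ses(self) -> dict[str, float]:
        return {name: t.drug_cost_se for name, t in self.treatments.items()}

    def ae_drug_cost_ses(self) -> dict[str, float]:
        return {name: c.cost_se for name, c in self.ae_drug_costs.items()}

    def wtp_grid(self):
        import numpy as np

        return np.arange(0.0, self.wtp_grid_max + self.wtp_grid_step / 2, self.wtp_grid_step)


def load_config(path: str | Path) -> ModelConfig:
    """Load and fully validate a YAML (or JSON) configuration file."""
    path = Path(path)
    if not path.exists():
        raise ModelValidationError(f"configuration file not found: {path}")
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ModelValidationError(f"{path}: configuration must be a mapping")
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ModelValidationError(f"{path}: {exc}") from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration as YAML; round-trips through load_config."""
    payload = config.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def default_config() -> ModelConfig:
    """The packaged configuration with the published Jordanian inputs."""
    resource = importlib.resources.files("cohortcea").joinpath("data/default.yaml")
    raw = yaml.safe_load(resource.read_text(encoding="utf-8"))
    return ModelConfig.model_validate(raw)
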