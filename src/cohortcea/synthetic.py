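"""Synthetic model instances and the individual-level simulation oracle.

The generator emulates the statistical shape of the published inputs —
transition profiles on the 4-simplex with small standard errors, positively
skewed per-mg drug prices, annual adverse-event probabilities — so that
every stage of the pipeline is testable without external data.  The
microsimulation oracle propagates individual agents through the same
structural variants and provides empirical state frequencies against which
the cohort expectation model is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    AEDrugCostConfig,
    AEManagementConfig,
    DoseConfig,
    ModelConfig,
    PSASettingsConfig,
    ServicesConfig,
    TransitionsConfig,
    TreatmentConfig,
)
from .costing import ADVERSE_EVENTS
from .econ import CEResult
from .errors import ConfigurationError
from .model import (
    HealthState,
    ModelSpec,
    StructuralVariant,
    TransitionProfile,
    build_transition_matrix,
)

__all__ = [
    "SyntheticSpec",
    "generate_model",
    "MicrosimTrace",
    "microsim_oracle",
    "known_answer_cases",
    "zero_se_config",
    "zero_cost_config",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic model generator.

    ``concentration`` scales the Dirichlet draw for the transition
    profiles (larger -> closer to the simplex centre, residuals safely
    positive); ``se_scale`` sets SEs as a fraction of the binomial bound
    sqrt(p(1-p)) and must stay below 1 for beta feasibility.
    """

    n_treatments: int = 4
    concentration: float = 8.0
    se_scale: float = 0.05
    drug_cost_range: tuple[float, float] = (0.002, 1.0)
    dose_range: tuple[float, float] = (2.0, 800.0)
    ae_probability_range: tuple[float, float] = (0.01, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatments < 1:
            raise ConfigurationError("n_treatments must be >= 1")
        if not 0.0 <= self.se_scale < 1.0:
            raise ConfigurationError("se_scale must be in [0, 1)")
        for low, high in (self.drug_cost_range, self.dose_range, self.ae_probability_range):
            if not 0 <= low <= high:
                raise ConfigurationError("ranges must satisfy 0 <= low <= high")


def generate_model(spec: SyntheticSpec) -> ModelConfig:
    """Generate a fully valid random model configuration.

    Deterministic in ``spec.seed``; every generated configuration passes
    the same schema validation as a hand-written one.
    """
    rng = np.random.default_rng(spec.seed)
    treatments = {}
    for index in range(spec.n_treatments):
        name = f"T{index + 1}"
        probs = rng.dirichlet(np.full(4, spec.concentration))
        ses = spec.se_scale * np.sqrt(probs * (1.0 - probs))
        ae = {
            event: float(rng.uniform(*spec.ae_probability_range))
            for event in ADVERSE_EVENTS
        }
        low_c, high_c = spec.drug_cost_range
        cost = float(np.exp(rng.uniform(np.log(max(low_c, 1e-6)), np.log(max(high_c, 1e-6)))))
        low_d, high_d = spec.dose_range
        maintenance = float(rng.uniform(low_d, high_d))
        titration = float(rng.uniform(low_d, maintenance))
        treatments[name] = TreatmentConfig(
            transitions=TransitionsConfig(
                p_sf=float(probs[0]), p_pr=float(probs[1]),
                p_nr=float(probs[2]), p_disc=float(probs[3]),
                se_sf=float(ses[0]), se_pr=float(ses[1]),
                se_nr=float(ses[2]), se_disc=float(ses[3]),
            ),
            ae_annual_probabilities=ae,
            dose=DoseConfig(
                titration_daily_dose_mg=titration,
                maintenance_daily_dose_mg=maintenance,
            ),
            drug_cost_per_mg=cost,
            drug_cost_se=0.25 * cost / 1.96,
        )
    return ModelConfig(
        treatments=treatments,
        reference="T1",
        psa=PSASettingsConfig(seed=int(rng.integers(0, 2**31 - 1))),
    )


@dataclass(frozen=True)
class MicrosimTrace:
    """Empirical trace from individual-level simulation.

    ``occupancy`` rows are exact frequencies (they sum to 1 by counting);
    ``se`` holds the binomial standard error of each occupancy entry and
    ``ever_sf_se`` that of the cumulative ever-seizure-free share.
    """

    treatment: str
    occupancy: np.ndarray
    ever_sf: np.ndarray
    se: np.ndarray
    ever_sf_se: np.ndarray
    n_agents: int


def microsim_oracle(
    profile: TransitionProfile,
    spec: ModelSpec,
    n_agents: int,
    seed: int,
) -> MicrosimTrace:
    """Simulate agents individually through the configured variant.

    This is an independent brute-force check of the cohort expectation
    model: each agent draws its cycle-1 outcome from the profile and then
    follows the transition matrix row of its current state.
    """
    if n_agents < 1:
        raise ConfigurationError("n_agents must be >= 1")
    rng = np.random.default_rng(seed)
    matrix = build_transition_matrix(profile, spec.structural_variant)
    cum_rows = np.cumsum(matrix, axis=1)
    base_cum = np.cumsum(profile.probabilities)

    n_states = len(HealthState)
    occupancy = np.empty((spec.n_cycles, n_states))
    ever_sf = np.empty(spec.n_cycles)

    states = np.searchsorted(base_cum, rng.random(n_agents), side="right")
    states = np.minimum(states, n_states - 1)
    ever = states == HealthState.SEIZURE_FREE
    occupancy[0] = np.bincount(states, minlength=n_states) / n_agents
    ever_sf[0] = ever.mean()
    for t in range(1, spec.n_cycles):
        u = rng.random(n_agents)
        states = (u[:, None] > cum_rows[states]).sum(axis=1)
        states = np.minimum(states, n_states - 1)
        ever |= states == HealthState.SEIZURE_FREE
        occupancy[t] = np.bincount(states, minlength=n_states) / n_agents
        ever_sf[t] = ever.mean()

    se = np.sqrt(occupancy * (1.0 - occupancy) / n_agents)
    ever_sf_se = np.sqrt(ever_sf * (1.0 - ever_sf) / n_agents)
    return MicrosimTrace(
        treatment=profile.treatment,
        occupancy=occupancy,
        ever_sf=ever_sf,
        se=se,
        ever_sf_se=ever_sf_se,
        n_agents=n_agents,
    )


def zero_se_config() -> ModelConfig:
    """Default configuration with every uncertainty parameter set to zero.

    A PSA on this configuration must reproduce the deterministic pipeline
    exactly in every iteration.
    """
    from .config import default_config

    config = default_config()
    treatments = {}
    for name, t in config.treatments.items():
        treatments[name] = t.model_copy(
            update={
                "transitions": t.transitions.model_copy(
                    update={"se_sf": 0.0, "se_pr": 0.0, "se_nr": 0.0, "se_disc": 0.0}
                ),
                "drug_cost_se": 0.0,
            }
        )
    return config.model_copy(
        update={
            "treatments": treatments,
            "services": config.services.model_copy(update={"cost_variation": 0.0}),
            "ae_drug_costs": {
                name: c.model_copy(update={"cost_se": 0.0})
                for name, c in config.ae_drug_costs.items()
            },
            "psa": config.psa.model_copy(
                update={"ae_probability_pct": 0.0, "discount_rate_se": 0.0}
            ),
        }
    )


def zero_cost_config() -> ModelConfig:
    """Default configuration with every unit cost set to zero."""
    from .config import default_config

    config = default_config()
    treatments = {
        name: t.model_copy(update={"drug_cost_per_mg": 0.0, "drug_cost_se": 0.0})
        for name, t in config.treatments.items()
    }
    return config.model_copy(
        update={
            "treatments": treatments,
            "services": ServicesConfig(
                inpatient_night=0, emergency_visit=0, neurologist_visit=0,
                gp_visit=0, eeg=0, cost_variation=0,
            ),
            "ae_drug_costs": {
                name: AEDrugCostConfig(cost_per_mg=0.0, cost_se=0.0)
                for name in config.ae_drug_costs
            },
        }
    )


def known_answer_cases() -> dict:
    """Degenerate and worked-example fixtures reused across the test suite."""
    rng = np.random.default_rng(12345)
    n_cloud = 4000
    # point-symmetric cloud about the origin: each quadrant share -> 1/4
    half = rng.normal(size=(n_cloud // 2, 2)) * np.array([0.1, 500.0])
    cloud = np.vstack([half, -half])
    return {
        "worked_example": [
            # published deterministic (cost JOD, complete-response) pairs
            CEResult("BRV", 3925.0, 0.5771),
            CEResult("ESL", 4139.0, 0.2870),
            CEResult("LCM", 3078.0, 0.2683),
            CEResult("PER", 5541.0, 0.3127),
        ],
        "certain_response": TransitionProfile("certain_response", 1.0, 0.0, 0.0, 0.0),
        "certain_discontinuation": TransitionProfile(
            "certain_discontinuation", 0.0, 0.0, 0.0, 1.0
        ),
        "symmetric_cloud": cloud,  # columns: delta_effect, delta_cost
        "zero_se_config": zero_se_config(),
        "zero_cost_config": zero_cost_config(),
    }
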