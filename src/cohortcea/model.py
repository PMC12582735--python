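"""Four-state Markov cohort model of adjunctive antiseizure treatment.

The cohort starts treatment-naive and realises a multinomial outcome each
3-month cycle: seizure freedom (complete response), partial response
(>=50% seizure-frequency reduction), non-response, or discontinuation of
the drug for any reason.  Per-cycle transition probabilities are treatment
specific and held constant over the horizon.  The effectiveness outcome is
the proportion of the cohort achieving complete response.

Because the published four-probability rows do not say which states stop
transitioning, three structural variants are provided:

* ``ABSORBING_SF_DISC`` (default) — seizure freedom and discontinuation are
  absorbing; partial and non-responders re-draw their outcome each cycle.
* ``ABSORBING_DISC_ONLY`` — only discontinuation is absorbing.
* ``REDRAW_ALL`` — every state re-draws from the same profile each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

from .errors import ConfigurationError, ModelValidationError

__all__ = [
    "HealthState",
    "StructuralVariant",
    "EffectDefinition",
    "TransitionProfile",
    "ModelSpec",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "effect_measure",
]

#: Tolerance below which an off-simplex profile is silently renormalised;
#: larger deviations raise.  Printed inputs sum to 1 exactly.
SIMPLEX_TOL = 1e-6


class HealthState(IntEnum):
    """The four mutually exclusive health states."""

    SEIZURE_FREE = 0
    PARTIAL_RESPONSE = 1
    NON_RESPONSE = 2
    DISCONTINUED = 3


class StructuralVariant(str, Enum):
    ABSORBING_SF_DISC = "absorbing_sf_disc"
    ABSORBING_DISC_ONLY = "absorbing_disc_only"
    REDRAW_ALL = "redraw_all"


class EffectDefinition(str, Enum):
    """How the complete-response proportion is read off the trace."""

    EVER_SF = "ever_sf"
    MEAN_SF_OCCUPANCY = "mean_sf_occupancy"
    TERMINAL_SF = "terminal_sf"


@dataclass(frozen=True)
class TransitionProfile:
    """One treatment's per-cycle outcome probabilities with standard errors.

    Probabilities are per 3-month cycle and must lie on the 4-simplex.
    Standard errors parameterise the beta distributions used in the
    probabilistic sensitivity analysis; ``se == 0`` means the parameter is
    fixed.
    """

    treatment: str
    p_sf: float
    p_pr: float
    p_nr: float
    p_disc: float
    se_sf: float = 0.0
    se_pr: float = 0.0
    se_nr: float = 0.0
    se_disc: float = 0.0

    def __post_init__(self) -> None:
        probs = np.array([self.p_sf, self.p_pr, self.p_nr, self.p_disc], float)
        ses = np.array([self.se_sf, self.se_pr, self.se_nr, self.se_disc], float)
        if np.any((probs < 0) | (probs > 1)):
            raise ModelValidationError(
                f"{self.treatment}: transition probabilities must lie in [0, 1], got {probs}"
            )
        total = probs.sum()
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ModelValidationError(
                f"{self.treatment}: transition probabilities sum to {total:.8f}, not 1"
            )
        if abs(total - 1.0) > 0:  # silent renormalisation inside tolerance
            probs = probs / total
            for name, value in zip(("p_sf", "p_pr", "p_nr", "p_disc"), probs):
                object.__setattr__(self, name, float(value))
        if np.any(ses < 0):
            raise ModelValidationError(f"{self.treatment}: standard errors must be >= 0")
        interior = (probs > 0) & (probs < 1)
        bound = probs * (1.0 - probs)
        if np.any(ses[interior] ** 2 >= bound[interior]):
            raise ModelValidationError(
                f"{self.treatment}: SE^2 must be < p(1-p) for interior probabilities"
            )

    @property
    def probabilities(self) -> np.ndarray:
        """Probability row ordered as :class:`HealthState`."""
        return np.array([self.p_sf, self.p_pr, self.p_nr, self.p_disc], float)

    @property
    def standard_errors(self) -> np.ndarray:
        return np.array([self.se_sf, self.se_pr, self.se_nr, self.se_disc], float)


@dataclass(frozen=True)
class ModelSpec:
    """Cycle structure and counting conventions of one model run."""

    cycle_length_days: int = 90
    n_cycles: int = 8
    structural_variant: StructuralVariant = StructuralVariant.ABSORBING_SF_DISC
    effect_definition: EffectDefinition = EffectDefinition.EVER_SF

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigurationError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.cycle_length_days <= 0:
            raise ConfigurationError("cycle_length_days must be positive")


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle plus the cumulative ever-seizure-free share.

    ``occupancy`` has one row per cycle (cycle 1 first) and one column per
    :class:`HealthState`; rows are probability vectors.  ``ever_sf[t]`` is
    the proportion of the cohort that has entered the seizure-free state at
    least once by the end of cycle ``t+1``; it is non-decreasing and, when
    seizure freedom is absorbing, equals the seizure-free occupancy.
    """

    treatment: str
    occupancy: np.ndarray
    ever_sf: np.ndarray
    variant: StructuralVariant = StructuralVariant.ABSORBING_SF_DISC

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, float)
        ever = np.asarray(self.ever_sf, float)
        if occ.ndim != 2 or occ.shape[1] != len(HealthState):
            raise ModelValidationError("occupancy must be (n_cycles, 4)")
        if ever.shape != (occ.shape[0],):
            raise ModelValidationError("ever_sf must have one entry per cycle")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ModelValidationError("occupancy entries must lie in [0, 1]")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-12:
            raise ModelValidationError("occupancy rows must sum to 1 within 1e-12")
        if np.any(np.diff(ever) < -1e-12):
            raise ModelValidationError("ever_sf must be non-decreasing")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "ever_sf", ever)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]


def build_transition_matrix(
    profile: TransitionProfile,
    variant: StructuralVariant = StructuralVariant.ABSORBING_SF_DISC,
) -> np.ndarray:
    """Return the 4x4 row-stochastic one-cycle transition matrix.

    Rows of absorbing states are identity rows; every other row is the
    treatment's outcome-probability vector (memoryless re-draw).
    """
    base = profile.probabilities
    matrix = np.tile(base, (len(HealthState), 1))
    if variant == StructuralVariant.ABSORBING_SF_DISC:
        absorbing = (HealthState.SEIZURE_FREE, HealthState.DISCONTINUED)
    elif variant == StructuralVariant.ABSORBING_DISC_ONLY:
        absorbing = (HealthState.DISCONTINUED,)
    elif variant == StructuralVariant.REDRAW_ALL:
        absorbing = ()
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown structural variant {variant!r}")
    for state in absorbing:
        matrix[state] = 0.0
        matrix[state, state] = 1.0
    return matrix


def run_cohort(spec: ModelSpec, profile: TransitionProfile) -> CohortTrace:
    """Propagate the cohort through ``spec.n_cycles`` cycles.

    The whole cohort realises its first multinomial outcome at cycle 1, so
    the first occupancy row equals the profile's probability vector; each
    later row is the previous row propagated through the transition matrix.

    ``ever_sf`` is accumulated from the inflow into the seizure-free state
    of the never-yet-seizure-free sub-cohort, which makes it a genuine
    first-passage proportion under every structural variant.
    """
    matrix = build_transition_matrix(profile, spec.structural_variant)
    base = profile.probabilities
    occupancy = np.empty((spec.n_cycles, len(HealthState)))
    ever_sf = np.empty(spec.n_cycles)

    occupancy[0] = base
    ever_sf[0] = base[HealthState.SEIZURE_FREE]
    # never-seizure-free pool, propagated with the same matrix
    pool = base.copy()
    pool[HealthState.SEIZURE_FREE] = 0.0
    for t in range(1, spec.n_cycles):
        occupancy[t] = occupancy[t - 1] @ matrix
        pool = pool @ matrix
        ever_sf[t] = ever_sf[t - 1] + pool[HealthState.SEIZURE_FREE]
        pool[HealthState.SEIZURE_FREE] = 0.0

    return CohortTrace(
        treatment=profile.treatment,
        occupancy=occupancy,
        ever_sf=ever_sf,
        variant=spec.structural_variant,
    )


def effect_measure(
    trace: CohortTrace,
    definition: EffectDefinition = EffectDefinition.EVER_SF,
) -> float:
    """Complete-response proportion of a trace under the chosen definition."""
    sf = trace.occupancy[:, HealthState.SEIZURE_FREE]
    if definition == EffectDefinition.EVER_SF:
        value = trace.ever_sf[-1]
    elif definition == EffectDefinition.MEAN_SF_OCCUPANCY:
        value = sf.mean()
    elif definition == EffectDefinition.TERMINAL_SF:
        value = sf[-1]
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown effect definition {definition!r}")
    return float(min(max(value, 0.0), 1.0))
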