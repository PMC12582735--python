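"""Discounting, incremental cost-effectiveness, dominance, net benefit.

The incremental cost-effectiveness ratio (ICER) divides the cost
difference in JOD by the complete-response difference expressed as a
proportion; because a 1-percentage-point gain is 0.01 on that scale, the
resulting number is conventionally read as "JOD per 1% complete response".
The willingness-to-pay threshold (JOD 9000, three times Jordanian GDP per
capita) is applied on the same scale.

Discounting is year-stepped: cycles falling in the second model year are
discounted by one year at the annual rate; there is no per-cycle
compounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ConfigurationError, ModelValidationError, UndefinedICERError

__all__ = [
    "DiscountSpec",
    "discount_factor",
    "CEResult",
    "Dominance",
    "IncrementalResult",
    "icer",
    "nmb",
]

CYCLES_PER_YEAR = 4


@dataclass(frozen=True)
class DiscountSpec:
    """Year-step discounting: outcomes in year 2 are discounted one year.

    ``annual_rate`` defaults to 3.5%; the probabilistic analysis varies it
    over ``psa_range`` (0–5%).
    """

    annual_rate: float = 0.035
    psa_range: tuple[float, float] = (0.0, 0.05)

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ConfigurationError("discount rate must be >= 0")
        low, high = self.psa_range
        if not low <= high:
            raise ConfigurationError("psa_range must be (low, high) with low <= high")


def discount_factor(
    cycle_index: int,
    spec: DiscountSpec,
    n_cycles: int = 8,
    cycles_per_year: int = CYCLES_PER_YEAR,
) -> float:
    """Discount factor for one cycle: 1 in year 1, 1/(1+r)^(y-1) in year y."""
    if not 1 <= cycle_index <= n_cycles:
        raise ConfigurationError(
            f"cycle_index must be in [1, {n_cycles}], got {cycle_index}"
        )
    year = (cycle_index - 1) // cycles_per_year
    return float(1.0 / (1.0 + spec.annual_rate) ** year)


@dataclass(frozen=True)
class CEResult:
    """Total discounted cost (JOD) and complete-response proportion."""

    treatment: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ModelValidationError(f"{self.treatment}: cost must be >= 0")
        if not 0.0 <= self.effect <= 1.0:
            raise ModelValidationError(f"{self.treatment}: effect must be in [0, 1]")


class Dominance(str, Enum):
    """ICER-plane quadrant of the intervention relative to the comparator.

    ``SAVING_SE`` (more effective, less costly) is the dominant,
    cost-saving class; ``DOMINATED`` its mirror image.  The two trade-off
    classes need a willingness-to-pay threshold to resolve.
    """

    SAVING_SE = "saving_se"
    TRADE_OFF_NE = "trade_off_ne"
    TRADE_OFF_SW = "trade_off_sw"
    DOMINATED = "dominated"


@dataclass(frozen=True)
class IncrementalResult:
    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float
    dominance: Dominance


def _classify(delta_effect: float, delta_cost: float) -> Dominance:
    # boundary rule: delta_cost == 0 counts toward the cost-saving side
    if delta_effect > 0:
        return Dominance.TRADE_OFF_NE if delta_cost > 0 else Dominance.SAVING_SE
    return Dominance.DOMINATED if delta_cost > 0 else Dominance.TRADE_OFF_SW


def icer(intervention: CEResult, comparator: CEResult) -> IncrementalResult:
    """Pairwise incremental analysis of intervention versus comparator.

    ``delta_effect`` is on the proportion scale; the ratio is undefined
    (raises :class:`UndefinedICERError`) when the effects are equal.
    """
    delta_cost = intervention.cost - comparator.cost
    delta_effect = intervention.effect - comparator.effect
    if delta_effect == 0.0:
        raise UndefinedICERError(
            f"ICER undefined for {intervention.treatment} vs {comparator.treatment}: "
            f"equal effects (delta cost {delta_cost:+.2f} JOD)",
            delta_cost=delta_cost,
        )
    return IncrementalResult(
        intervention=intervention.treatment,
        comparator=comparator.treatment,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=delta_cost / delta_effect,
        dominance=_classify(delta_effect, delta_cost),
    )


def nmb(result: CEResult, wtp: float) -> float:
    """Net monetary benefit, WTP x effect - cost, on matching scales."""
    if wtp < 0:
        raise ConfigurationError("willingness-to-pay must be >= 0")
    return wtp * result.effect - result.cost
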