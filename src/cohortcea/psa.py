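"""Second-order Monte Carlo probabilistic sensitivity analysis.

Every uncertain input is given a parametric distribution matched to its
published mean and standard error by the method of moments: beta for
probabilities (transition and adverse-event probabilities), gamma for
costs, and a beta rescaled to the stated 0–5% range for the discount
rate.  Costs whose uncertainty is stated as a +/-25% range get an SE of
0.25 x mean / 1.96, reading the range as a 95% interval half-width.

Each of the (default 2000) iterations draws one value for every parameter,
re-runs the deterministic cohort/costing pipeline for every treatment, and
records the (cost, effect) pair.  Quadrant tallies on the incremental
cost-effectiveness plane and cost-effectiveness acceptability curves
(CEAC) are derived from the iteration table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .costing import ADVERSE_EVENTS, AEProfile, CostModel, UnitCosts, total_expected_cost
from .econ import CEResult, DiscountSpec, nmb
from .errors import (
    ConfigurationError,
    InfeasibleMomentsError,
    ModelValidationError,
    SamplingInfeasibleError,
)
from .model import ModelSpec, TransitionProfile, effect_measure, run_cohort

__all__ = [
    "PSAConfig",
    "PSAResult",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "se_from_pct_range",
    "draw_beta",
    "draw_gamma",
    "draw_scaled_beta",
    "sample_transition_profile",
    "run_psa",
    "icer_plane_quadrants",
    "ceac",
]

_REJECTION_CAP = 1000


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a mean and SE.

    Method of moments: alpha = mean*k, beta = (1-mean)*k with
    k = mean(1-mean)/se^2 - 1.
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must be in (0, 1), got {mean}")
    if se <= 0:
        raise InfeasibleMomentsError(f"beta SE must be > 0, got {se}")
    bound = mean * (1.0 - mean)
    if se * se >= bound:
        raise InfeasibleMomentsError(
            f"SE^2 = {se*se:.3g} >= mean(1-mean) = {bound:.3g}: no beta matches"
        )
    k = bound / (se * se) - 1.0
    return mean * k, (1.0 - mean) * k


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and SE: mean^2/se^2, se^2/mean."""
    if mean <= 0 or se <= 0:
        raise InfeasibleMomentsError(
            f"gamma requires mean > 0 and SE > 0, got mean={mean}, se={se}"
        )
    return mean * mean / (se * se), se * se / mean


def se_from_pct_range(mean: float, pct: float = 0.25) -> float:
    """SE implied by a +/-pct range read as a 95% interval half-width."""
    if mean <= 0:
        raise InfeasibleMomentsError(f"mean must be > 0, got {mean}")
    if pct < 0:
        raise ConfigurationError("pct must be >= 0")
    return pct * mean / 1.959963984540054


def draw_beta(mean: float, se: float, rng: np.random.Generator, size=None):
    """Beta draw with the given moments; SE of 0 is the degenerate point mass."""
    if se == 0.0:
        return mean if size is None else np.full(size, mean)
    alpha, beta = beta_from_mean_se(mean, se)
    return rng.beta(alpha, beta, size=size)


def draw_gamma(mean: float, se: float, rng: np.random.Generator, size=None):
    """Gamma draw with the given moments; SE of 0 is the degenerate point mass."""
    if se == 0.0 or mean == 0.0:
        return mean if size is None else np.full(size, mean)
    shape, scale = gamma_from_mean_se(mean, se)
    return rng.gamma(shape, scale, size=size)


def draw_scaled_beta(
    mean: float,
    se: float,
    low: float,
    high: float,
    rng: np.random.Generator,
    size=None,
):
    """Beta on [low, high], moment-matched on the affinely rescaled scale."""
    if not low < high:
        raise ConfigurationError("scaled beta requires low < high")
    width = high - low
    raw = draw_beta((mean - low) / width, se / width, rng, size=size)
    return low + width * raw


def sample_transition_profile(
    profile: TransitionProfile, rng: np.random.Generator
) -> TransitionProfile:
    """One PSA draw of a transition profile.

    Seizure-free, partial-response and discontinuation probabilities are
    drawn from their beta distributions; the non-response probability is
    the simplex residual.  Draws with a negative residual are rejected and
    redrawn (capped), so every returned profile is a valid simplex point.
    """
    if profile.se_sf == profile.se_pr == profile.se_disc == 0.0:
        return profile
    for _ in range(_REJECTION_CAP):
        p_sf = float(draw_beta(profile.p_sf, profile.se_sf, rng))
        p_pr = float(draw_beta(profile.p_pr, profile.se_pr, rng))
        p_disc = float(draw_beta(profile.p_disc, profile.se_disc, rng))
        p_nr = 1.0 - (p_sf + p_pr + p_disc)
        if p_nr >= 0.0:
            return TransitionProfile(
                treatment=profile.treatment,
                p_sf=p_sf,
                p_pr=p_pr,
                p_nr=p_nr,
                p_disc=p_disc,
            )
    raise SamplingInfeasibleError(
        f"{profile.treatment}: {_REJECTION_CAP} draws all left the simplex"
    )


@dataclass(frozen=True)
class PSAConfig:
    """Iteration count, seed, and reference treatment of one PSA run."""

    n_iterations: int = 2000
    seed: int = 0
    reference: str = "BRV"
    #: SE for AE annual probabilities as a fraction of the mean over 1.96;
    #: mirrors the +/-25% cost-uncertainty convention.
    ae_probability_pct: float = 0.25
    #: SE of the discount rate on the rate scale; default is a quarter of
    #: the half-width of the 0-5% range.
    discount_rate_se: float = 0.00625

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")


@dataclass(frozen=True)
class PSAResult:
    """Iteration table plus the settings that produced it.

    ``iterations`` has columns iteration, treatment, cost, effect with one
    row per (iteration, treatment).
    """

    iterations: pd.DataFrame
    reference: str
    seed: int

    @property
    def treatments(self) -> list[str]:
        return list(self.iterations["treatment"].unique())

    def pair(self, intervention: str, comparator: str) -> pd.DataFrame:
        """Per-iteration (delta_effect, delta_cost) of one pairwise contrast."""
        wide_c = self.iterations.pivot(index="iteration", columns="treatment", values="cost")
        wide_e = self.iterations.pivot(index="iteration", columns="treatment", values="effect")
        for name in (intervention, comparator):
            if name not in wide_c.columns:
                raise ModelValidationError(f"treatment {name!r} not in PSA result")
        return pd.DataFrame(
            {
                "delta_effect": wide_e[intervention] - wide_e[comparator],
                "delta_cost": wide_c[intervention] - wide_c[comparator],
            }
        )

    def summary(self) -> pd.DataFrame:
        """Mean cost and effect per treatment over iterations."""
        return (
            self.iterations.groupby("treatment")[["cost", "effect"]]
            .mean()
            .reset_index()
        )


def _sampled_unit_costs(
    unit: UnitCosts,
    cost_ses: dict[str, float],
    ae_cost_ses: dict[str, float],
    rng: np.random.Generator,
) -> UnitCosts:
    pct = unit.cost_variation
    return replace(
        unit,
        drug_cost_per_mg={
            name: float(draw_gamma(mean, cost_ses.get(name, 0.0), rng))
            for name, mean in unit.drug_cost_per_mg.items()
        },
        ae_drug_cost_per_mg={
            name: float(draw_gamma(mean, ae_cost_ses.get(name, 0.0), rng))
            for name, mean in unit.ae_drug_cost_per_mg.items()
        },
        inpatient_night=_service_draw(unit.inpatient_night, pct, rng),
        emergency_visit=_service_draw(unit.emergency_visit, pct, rng),
        neurologist_visit=_service_draw(unit.neurologist_visit, pct, rng),
        gp_visit=_service_draw(unit.gp_visit, pct, rng),
        eeg=_service_draw(unit.eeg, pct, rng),
    )


def _service_draw(mean: float, pct: float, rng: np.random.Generator) -> float:
    if mean == 0.0 or pct == 0.0:
        return mean
    return float(draw_gamma(mean, se_from_pct_range(mean, pct), rng))


def _sampled_ae_profile(
    ae: AEProfile, pct: float, rng: np.random.Generator
) -> AEProfile:
    drawn = {}
    for event in ADVERSE_EVENTS:
        p = ae.annual_probability(event)
        se = 0.0 if pct == 0.0 or p in (0.0, 1.0) else pct * p / 1.959963984540054
        drawn[event] = float(draw_beta(p, se, rng))
    return AEProfile(treatment=ae.treatment, **drawn)


def run_psa(
    profiles: dict[str, TransitionProfile],
    cost_models: dict[str, CostModel],
    model_spec: ModelSpec,
    discount: DiscountSpec,
    psa: PSAConfig,
    cost_ses: dict[str, float] | None = None,
    ae_cost_ses: dict[str, float] | None = None,
) -> PSAResult:
    """Run the full second-order Monte Carlo simulation.

    ``cost_ses`` / ``ae_cost_ses`` carry the published SEs of the per-mg
    drug prices (absent entries are treated as fixed).  Service costs use
    the +/-``cost_variation`` convention of their :class:`UnitCosts`.
    Reproducible: the same seed yields a bit-identical iteration table.
    """
    if set(profiles) != set(cost_models):
        raise ConfigurationError("profiles and cost_models must cover the same treatments")
    if psa.reference not in profiles:
        raise ConfigurationError(f"reference treatment {psa.reference!r} not configured")
    cost_ses = cost_ses or {}
    ae_cost_ses = ae_cost_ses or {}
    rng = np.random.default_rng(psa.seed)
    low, high = discount.psa_range
    treatments = sorted(profiles)

    records = []
    for iteration in range(psa.n_iterations):
        try:
            if psa.discount_rate_se > 0 and low < high:
                rate = float(
                    draw_scaled_beta(
                        discount.annual_rate, psa.discount_rate_se, low, high, rng
                    )
                )
            else:
                rate = discount.annual_rate
            disc_i = DiscountSpec(annual_rate=rate, psa_range=discount.psa_range)
            for name in treatments:
                cm = cost_models[name]
                profile_i = sample_transition_profile(profiles[name], rng)
                unit_i = _sampled_unit_costs(cm.unit_costs, cost_ses, ae_cost_ses, rng)
                ae_i = _sampled_ae_profile(cm.ae_profile, psa.ae_probability_pct, rng)
                cm_i = replace(cm, unit_costs=unit_i, ae_profile=ae_i)
                trace = run_cohort(model_spec, profile_i)
                effect = effect_measure(trace, model_spec.effect_definition)
                cost = total_expected_cost(
                    trace, cm_i, disc_i, model_spec.cycle_length_days
                )
                records.append(
                    {
                        "iteration": iteration,
                        "treatment": name,
                        "cost": cost,
                        "effect": effect,
                    }
                )
        except (ModelValidationError, InfeasibleMomentsError, SamplingInfeasibleError) as exc:
            raise SamplingInfeasibleError(
                f"PSA iteration {iteration} failed: {exc}"
            ) from exc

    table = pd.DataFrame.from_records(
        records, columns=["iteration", "treatment", "cost", "effect"]
    )
    return PSAResult(iterations=table, reference=psa.reference, seed=psa.seed)


def icer_plane_quadrants(
    result: PSAResult,
    intervention: str,
    comparator: str,
) -> dict[str, float]:
    """Fractions of PSA iterations in each incremental-plane quadrant.

    NE: more effective, more costly (trade-off); SE: more effective, less
    costly (cost-saving); NW: less effective, more costly (dominated);
    SW: less effective, less costly.  Boundary rule: a zero cost
    difference counts toward the cost-saving (southern) side, a zero
    effect difference toward the non-effective (western) side.
    """
    pair = result.pair(intervention, comparator)
    de = pair["delta_effect"].to_numpy()
    dc = pair["delta_cost"].to_numpy()
    east = de > 0
    north = dc > 0
    n = len(de)
    return {
        "NE": float(np.mean(east & north)),
        "SE": float(np.mean(east & ~north)),
        "NW": float(np.mean(~east & north)),
        "SW": float(np.mean(~east & ~north)),
    }


def ceac(
    result: PSAResult,
    wtp_grid,
    intervention: str | None = None,
    comparators: list[str] | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve per pairwise comparator.

    For each willingness-to-pay value, the fraction of iterations in which
    the intervention's net monetary benefit exceeds the comparator's.
    """
    wtp_grid = np.asarray(list(wtp_grid), float)
    if wtp_grid.size == 0:
        raise ConfigurationError("wtp_grid must be nonempty")
    if np.any(wtp_grid < 0):
        raise ConfigurationError("wtp values must be >= 0")
    intervention = intervention or result.reference
    comparators = comparators or [t for t in result.treatments if t != intervention]

    rows = []
    for comparator in comparators:
        pair = result.pair(intervention, comparator)
        de = pair["delta_effect"].to_numpy()
        dc = pair["delta_cost"].to_numpy()
        for wtp in wtp_grid:
            prob = float(np.mean(wtp * de - dc > 0))
            rows.append({"wtp": float(wtp), "comparator": comparator, "probability": prob})
    return pd.DataFrame(rows)
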