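"""End-to-end drivers: deterministic analysis, PSA, CEAC, and CSV export."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import ModelConfig
from .costing import cost_breakdown, total_expected_cost
from .econ import CEResult, icer
from .errors import UndefinedICERError
from .model import CohortTrace, HealthState, effect_measure, run_cohort
from .psa import PSAResult, ceac, icer_plane_quadrants, run_psa

__all__ = [
    "evaluate_treatment",
    "run_deterministic",
    "deterministic_table",
    "run_pipeline",
    "trace_frame",
]

logger = logging.getLogger("cohortcea")


def evaluate_treatment(config: ModelConfig, treatment: str) -> tuple[CEResult, CohortTrace]:
    """Deterministic (cost, effect) of one treatment under the config."""
    spec = config.model_spec()
    trace = run_cohort(spec, config.transition_profile(treatment))
    effect = effect_measure(trace, spec.effect_definition)
    cost = total_expected_cost(
        trace, config.cost_model(treatment), config.discount_spec(), spec.cycle_length_days
    )
    return CEResult(treatment=treatment, cost=cost, effect=effect), trace


def run_deterministic(config: ModelConfig) -> dict[str, CEResult]:
    """Deterministic pipeline for every configured treatment."""
    return {name: evaluate_treatment(config, name)[0] for name in config.treatments}


def deterministic_table(results: dict[str, CEResult], reference: str) -> pd.DataFrame:
    """Pairwise incremental table with the reference treatment on top.

    ICERs are reported to the nearest JOD and effects as percentages with
    two decimals; the ICER column is conventionally read as JOD per 1%
    complete response.
    """
    rows = [
        {
            "treatment": reference,
            "cost": round(results[reference].cost, 2),
            "effect_pct": round(100 * results[reference].effect, 2),
            "comparator": "",
            "delta_cost": None,
            "delta_effect_pct": None,
            "icer": None,
            "dominance": "",
        }
    ]
    for name, result in results.items():
        if name == reference:
            continue
        try:
            inc = icer(results[reference], result)
            rows.append(
                {
                    "treatment": name,
                    "cost": round(result.cost, 2),
                    "effect_pct": round(100 * result.effect, 2),
                    "comparator": reference,
                    "delta_cost": round(inc.delta_cost, 2),
                    "delta_effect_pct": round(100 * inc.delta_effect, 1),
                    "icer": round(inc.icer),
                    "dominance": inc.dominance.value,
                }
            )
        except UndefinedICERError as exc:
            rows.append(
                {
                    "treatment": name,
                    "cost": round(result.cost, 2),
                    "effect_pct": round(100 * result.effect, 2),
                    "comparator": reference,
                    "delta_cost": round(exc.delta_cost, 2),
                    "delta_effect_pct": 0.0,
                    "icer": None,
                    "dominance": "undefined",
                }
            )
    return pd.DataFrame(rows)


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Long-format trace: columns cycle, state, proportion, ever_sf."""
    rows = []
    for cycle in range(1, trace.n_cycles + 1):
        for state in HealthState:
            rows.append(
                {
                    "cycle": cycle,
                    "state": state.name,
                    "proportion": trace.occupancy[cycle - 1, state],
                    "ever_sf": trace.ever_sf[cycle - 1],
                }
            )
    return pd.DataFrame(rows)


def _write_plots(psa_result: PSAResult, ceac_table: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reference = psa_result.reference
    fig, ax = plt.subplots(figsize=(7, 5))
    for comparator in (t for t in psa_result.treatments if t != reference):
        pair = psa_result.pair(reference, comparator)
        ax.scatter(
            100 * pair["delta_effect"], pair["delta_cost"], s=4, alpha=0.4,
            label=f"{reference} vs {comparator}",
        )
    ax.axhline(0, color="black", lw=0.8)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("Incremental complete response (percentage points)")
    ax.set_ylabel("Incremental cost (JOD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "icer_plane.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    for comparator, sub in ceac_table.groupby("comparator"):
        ax.plot(sub["wtp"], sub["probability"], label=f"{reference} vs {comparator}")
    ax.set_xlabel("Willingness to pay (JOD per 1% complete response)")
    ax.set_ylabel(f"Probability {reference} cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "ceac.png", dpi=150)
    plt.close(fig)


def run_pipeline(
    config: ModelConfig,
    mode: str = "deterministic",
    out_dir: str | Path = "results",
    seed: int | None = None,
    n_iterations: int | None = None,
    make_plots: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run one analysis mode and write its CSV outputs.

    Modes: ``deterministic`` (cohort traces, cost breakdowns, incremental
    table), ``psa`` (iteration table, plane-quadrant summary), ``ceac``
    (PSA plus acceptability curves).  Returns the tables it wrote, keyed
    by file stem.
    """
    if mode not in ("deterministic", "psa", "ceac"):
        raise ValueError(f"unknown mode {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}

    results = run_deterministic(config)
    table = deterministic_table(results, config.reference)
    table.to_csv(out_dir / "deterministic_results.csv", index=False)
    outputs["deterministic_results"] = table
    logger.info("deterministic results:\n%s", table.to_string(index=False))

    if mode == "deterministic":
        spec = config.model_spec()
        for name in config.treatments:
            _, trace = evaluate_treatment(config, name)
            tf = trace_frame(trace)
            tf.to_csv(out_dir / f"trace_{name}.csv", index=False)
            outputs[f"trace_{name}"] = tf
            bd = cost_breakdown(
                trace, config.cost_model(name), config.discount_spec(), spec.cycle_length_days
            )
            bd.to_csv(out_dir / f"costs_{name}.csv", index=False)
            outputs[f"costs_{name}"] = bd
        return outputs

    psa_cfg = config.psa_config(seed=seed, n_iterations=n_iterations)
    logger.info("running PSA: %d iterations, seed %d", psa_cfg.n_iterations, psa_cfg.seed)
    psa_result = run_psa(
        config.transition_profiles(),
        config.cost_models(),
        config.model_spec(),
        config.discount_spec(),
        psa_cfg,
        cost_ses=config.drug_cost_ses(),
        ae_cost_ses=config.ae_drug_cost_ses(),
    )
    psa_result.iterations.to_csv(out_dir / "psa_iterations.csv", index=False)
    outputs["psa_iterations"] = psa_result.iterations
    summary = psa_result.summary()
    summary.to_csv(out_dir / "psa_summary.csv", index=False)
    outputs["psa_summary"] = summary

    quadrant_rows = []
    for comparator in (t for t in psa_result.treatments if t != config.reference):
        fractions = icer_plane_quadrants(psa_result, config.reference, comparator)
        quadrant_rows.append({"comparator": comparator, **fractions})
    quadrants = pd.DataFrame(quadrant_rows)
    quadrants.to_csv(out_dir / "psa_quadrants.csv", index=False)
    outputs["psa_quadrants"] = quadrants
    logger.info("ICER-plane quadrant shares:\n%s", quadrants.to_string(index=False))

    if mode == "ceac":
        ceac_table = ceac(psa_result, config.wtp_grid())
        ceac_table.to_csv(out_dir / "ceac.csv", index=False)
        outputs["ceac"] = ceac_table
        if make_plots:
            _write_plots(psa_result, ceac_table, out_dir)
    return outputs
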