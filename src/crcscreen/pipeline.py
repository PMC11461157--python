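"""End-to-end pipeline steps: base case, threshold grid, scenario discovery.

Each step is a function over a :class:`RunConfig` that writes CSV/JSON
outputs (with seed and config-hash provenance headers) and returns the
in-memory objects, so the analysis drivers, tests and the CLI share one code
path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cea import (EconParams, compute_frontier, net_monetary_benefit,
                  summaries_to_frame, summarize_outcomes)
from .config import RunConfig
from .discovery import (contours_to_json, extract_contours, fit_nmb_surface,
                        rank_importance)
from .nathist import Cohort, simulate_cohort
from .screening import run_strategy
from .threshold import build_scenario_grid, evaluate_scenarios, results_to_frame


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed} config={config.config_hash()}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    """Read back a pipeline CSV, skipping the provenance header."""
    return pd.read_csv(path, comment="#")


def build_cohort(config: RunConfig) -> Cohort:
    return simulate_cohort(config.natural_history, config.life_table,
                           config.cohort_n, config.seed)


def run_base_case(config: RunConfig, cohort: Optional[Cohort] = None,
                  write: bool = True):
    """Evaluate the configured strategies on one cohort; emit the results
    table (one row per strategy) and an event-log sample."""
    config.validate()
    cohort = cohort or build_cohort(config)
    outcomes = {}
    for strat in config.strategies:
        outcomes[strat.name] = run_strategy(cohort, strat, config.colonoscopy,
                                            config.econ)
    no_screen_name = next(
        (s.name for s in config.strategies if s.primary_test is None),
        config.strategies[0].name)
    no_screen = outcomes[no_screen_name]
    summaries = [summarize_outcomes(o, no_screen, config.econ)
                 for o in outcomes.values()]
    frontier = compute_frontier(summaries, config.econ)
    table = summaries_to_frame(summaries, frontier)
    if write:
        out = config.output_dir
        _write_csv(table, out / "summary.csv", config)
        frontier_df = pd.DataFrame([
            {"strategy": s.strategy, "status": frontier.status[s.strategy],
             "icer_per_qalyg": frontier.icer[s.strategy],
             "nmb_per_person": frontier.nmb[s.strategy]}
            for s in frontier.summaries])
        _write_csv(frontier_df, out / "frontier.csv", config)
        sample = pd.DataFrame(
            [{"person_id": e.person_id, "age": round(e.age, 3),
              "event": e.event, "detail": e.detail}
             for o in outcomes.values() for e in o.events[:2000]])
        _write_csv(sample, out / "events_sample.csv", config)
    return summaries, frontier, outcomes


def run_threshold(config: RunConfig, cohort: Optional[Cohort] = None,
                  write: bool = True, progress: bool = False,
                  models: int = 1) -> pd.DataFrame:
    """Evaluate the factorial scenario grid; one row per scenario (and per
    natural-history parameter set when ``models`` > 1)."""
    config.validate()
    from dataclasses import replace

    from .screening import colonoscopy_10y, fit_annual, no_screening

    grid = build_scenario_grid(config.scenario_spec)
    frames = []
    for m in range(models):
        # parameter-set replicates mimic cross-model ranges by perturbing the
        # onset rate a few percent; replicate 0 is the shipped calibration
        params = config.natural_history
        if m > 0:
            params = replace(params,
                             baseline_onset_rate=params.baseline_onset_rate
                             * (1.0 + 0.05 * (1 if m % 2 else -1) * ((m + 1) // 2)))
        c = (cohort if (m == 0 and cohort is not None)
             else simulate_cohort(params, config.life_table, config.cohort_n,
                                  config.seed + m))
        comparators = {
            "no_screen": run_strategy(c, no_screening(), config.colonoscopy,
                                      config.econ, collect_events=False),
            "fit": run_strategy(c, fit_annual(), config.colonoscopy,
                                config.econ, collect_events=False),
            "colonoscopy": run_strategy(c, colonoscopy_10y(), config.colonoscopy,
                                        config.econ, collect_events=False),
        }
        results = evaluate_scenarios(grid, c, comparators, config.econ,
                                     config.colonoscopy, progress=progress)
        frames.append(results_to_frame(results, model_label=f"m{m}"))
    table = pd.concat(frames, ignore_index=True)
    if write:
        _write_csv(table, config.output_dir / "scenarios.csv", config)
    return table


def run_discovery(config: RunConfig, scenario_table: Optional[pd.DataFrame] = None,
                  write: bool = True, grid_n: int = 10_000,
                  span: float = 0.5):
    """Random-forest importance ranking + smoothed NMB surface + contours."""
    config.validate()
    if scenario_table is None:
        path = config.output_dir / "scenarios.csv"
        if path.exists():
            scenario_table = read_output_csv(path)
        else:
            scenario_table = run_threshold(config, write=write)
    ranking = rank_importance(scenario_table, "cost_effective",
                              seed=config.seed)
    top3 = [v for v in ranking.order if v != "crc_sens"][:3]
    conditioning = {"crc_sens": max(config.scenario_spec.crc_sens_levels)}
    surface = fit_nmb_surface(scenario_table, vars=tuple(top3),
                              grid_n=grid_n, conditioning=conditioning,
                              span=span)

    # colonoscopy reference NMB on the same cohort
    _, frontier, _ = run_base_case(config, write=False)
    col_nmb = next((frontier.nmb[name] for name in frontier.nmb
                    if "colonoscopy" in name), None)
    surface.reference_level = col_nmb
    z = surface.table["nmb_smoothed"]
    levels = list(np.linspace(z.min(), z.max(), 7)[1:-1])
    contours = extract_contours(surface, levels, reference_level=col_nmb)

    if write:
        out = config.output_dir
        imp_df = pd.DataFrame(
            [{"variable": v, "gini_importance": s, "rank": r}
             for v, s, r in ranking.entries])
        _write_csv(imp_df, out / "importance.csv", config)
        _write_csv(surface.table, out / "nmb_surface.csv", config)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "contours.json", "w") as fh:
            json.dump(contours_to_json(contours), fh)
    return ranking, surface, contours
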