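"""Full-factorial threshold analysis of blood-test characteristics.

The default design crosses CRC sensitivity (74/83/92%), advanced-adenoma
sensitivity (10-50% by 10), screening interval (1-3 years) and unit cost
($25-$500 by $25) at fixed 90% specificity — 900 scenarios.  Each scenario's
blood-test regimen is evaluated on the shared cohort (common random numbers)
against no screening, annual FIT and decennial colonoscopy, and classified by
the cost-effectiveness footnote rule: cost-effective iff not dominated and
ICER below $150,000 per QALY gained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .cea import (EconParams, FrontierResult, OutcomeSummary, STATUS_DOMINATED,
                  STATUS_EXTENDED, compute_frontier, net_monetary_benefit,
                  summarize_outcomes)
from .errors import ConfigurationError
from .nathist import Cohort
from .screening import (ColonoscopyProfile, StrategyOutcome, blood_strategy,
                        run_strategy)

CE_DOMINATED = "dominated"
CE_EXTENDED = "extended_dominated"
CE_UNDER_CAP = "cost_effective_under_150k"
CE_ABOVE_CAP = "efficient_above_150k"

DEFAULT_WTP_CAP = 150_000.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Factor levels of the factorial design (specificity held fixed)."""

    crc_sens_levels: tuple[float, ...] = (0.74, 0.83, 0.92)
    aa_sens_levels: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)
    intervals: tuple[float, ...] = (1.0, 2.0, 3.0)
    costs: tuple[float, ...] = tuple(25.0 * k for k in range(1, 21))
    specificity: float = 0.90

    def validate(self) -> None:
        for name in ("crc_sens_levels", "aa_sens_levels", "intervals", "costs"):
            levels = getattr(self, name)
            if not levels:
                raise ConfigurationError(f"{name} must be nonempty")
            if len(set(levels)) != len(levels):
                raise ConfigurationError(f"{name} contains duplicate levels")
            if list(levels) != sorted(levels):
                raise ConfigurationError(f"{name} must be sorted ascending")

    @property
    def size(self) -> int:
        return (len(self.crc_sens_levels) * len(self.aa_sens_levels)
                * len(self.intervals) * len(self.costs))


@dataclass(frozen=True)
class Scenario:
    id: str
    crc_sens: float
    aa_sens: float
    interval: float
    cost: float
    specificity: float = 0.90


def build_scenario_grid(spec: ScenarioSpec) -> list[Scenario]:
    """Cartesian product with deterministic ordering: cost varies fastest,
    then AA sensitivity, then interval, then CRC sensitivity."""
    spec.validate()
    grid = []
    for crc, interval, aa, cost in itertools.product(
            spec.crc_sens_levels, spec.intervals, spec.aa_sens_levels, spec.costs):
        sid = f"crc{round(crc * 100):02d}_aa{round(aa * 100):02d}_int{interval:g}_c{cost:g}"
        grid.append(Scenario(sid, crc, aa, interval, cost, spec.specificity))
    return grid


@dataclass
class ScenarioResult:
    scenario: Scenario
    summary: OutcomeSummary
    nmb: float
    effectiveness_noninferior_vs_fit: bool
    effectiveness_noninferior_vs_col: bool
    nmb_noninferior_vs_col: bool
    ce_status: str


def classify_scenario(summary: OutcomeSummary, frontier: FrontierResult,
                      wtp_cap: float = DEFAULT_WTP_CAP) -> str:
    """Cost-effectiveness label: not dominated and ICER under the cap.

    The least effective non-dominated strategy carries no ICER and counts as
    cost-effective under the cap (it is weakly preferred to doing nothing).
    """
    status = frontier.status[summary.strategy]
    if status == STATUS_DOMINATED:
        return CE_DOMINATED
    if status == STATUS_EXTENDED:
        return CE_EXTENDED
    icer = frontier.icer[summary.strategy]
    if icer is None or icer < wtp_cap:
        return CE_UNDER_CAP
    return CE_ABOVE_CAP


def evaluate_scenarios(grid: Sequence[Scenario], cohort: Cohort,
                       comparators: dict[str, StrategyOutcome],
                       econ: EconParams | None = None,
                       colo: ColonoscopyProfile | None = None,
                       wtp_cap: float = DEFAULT_WTP_CAP,
                       model_label: Optional[str] = None,
                       progress: bool = False) -> list[ScenarioResult]:
    """Run every scenario's blood-test regimen on the shared cohort and
    classify it against {no screening, FIT, colonoscopy}.

    ``comparators`` must contain StrategyOutcomes under keys ``no_screen``,
    ``fit`` and ``colonoscopy``, all produced from ``cohort``.
    """
    econ = econ or EconParams()
    colo = colo or ColonoscopyProfile()
    for key in ("no_screen", "fit", "colonoscopy"):
        if key not in comparators:
            raise ConfigurationError(f"comparators must include '{key}'")
    no_screen = comparators["no_screen"]
    fit_summary = summarize_outcomes(comparators["fit"], no_screen, econ)
    col_summary = summarize_outcomes(comparators["colonoscopy"], no_screen, econ)
    ns_summary = summarize_outcomes(no_screen, no_screen, econ)
    col_nmb = net_monetary_benefit(col_summary, econ)

    results = []
    for k, sc in enumerate(grid):
        strat = blood_strategy(sc.crc_sens, sc.aa_sens, sc.interval, sc.cost,
                               sc.specificity, name=sc.id)
        outcome = run_strategy(cohort, strat, colo, econ, collect_events=False)
        summary = summarize_outcomes(outcome, no_screen, econ)
        frontier = compute_frontier(
            [ns_summary, fit_summary, col_summary, summary], econ)
        nmb = net_monetary_benefit(summary, econ)
        results.append(ScenarioResult(
            scenario=sc,
            summary=summary,
            nmb=nmb,
            effectiveness_noninferior_vs_fit=(
                summary.qalyg_per_1000 >= fit_summary.qalyg_per_1000),
            effectiveness_noninferior_vs_col=(
                summary.qalyg_per_1000 >= col_summary.qalyg_per_1000),
            nmb_noninferior_vs_col=nmb >= col_nmb,
            ce_status=classify_scenario(summary, frontier, wtp_cap),
        ))
        if progress and (k + 1) % 25 == 0:
            print(f"  evaluated {k + 1}/{len(grid)} scenarios", flush=True)
    if model_label is not None:
        for r in results:
            r.model = model_label  # type: ignore[attr-defined]
    return results


def results_to_frame(results: Sequence[ScenarioResult],
                     model_label: Optional[str] = None) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "scenario_id": r.scenario.id,
            "crc_sens": r.scenario.crc_sens,
            "aa_sens": r.scenario.aa_sens,
            "interval": r.scenario.interval,
            "cost": r.scenario.cost,
            "model": getattr(r, "model", model_label or "default"),
            "crc_cases_per_1000": r.summary.crc_cases_per_1000,
            "crc_deaths_per_1000": r.summary.crc_deaths_per_1000,
            "lyg_per_1000": r.summary.lyg_per_1000,
            "qalyg_per_1000": r.summary.qalyg_per_1000,
            "cost_per_person": r.summary.total_cost_per_person,
            "net_cost_per_person": r.summary.net_cost_per_person,
            "nmb": r.nmb,
            "eff_noninferior_vs_fit": r.effectiveness_noninferior_vs_fit,
            "eff_noninferior_vs_col": r.effectiveness_noninferior_vs_col,
            "nmb_noninferior_vs_col": r.nmb_noninferior_vs_col,
            "ce_status": r.ce_status,
            "cost_effective": r.ce_status == CE_UNDER_CAP,
        })
    return pd.DataFrame(rows)
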