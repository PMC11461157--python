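"""Cost-effectiveness analysis: discounting, per-strategy summaries vs no
screening, ICER frontier with strict and extended dominance, and net monetary
benefit.

Conventions: all costs and benefits are discounted to the cohort entry age
(45) at a constant annual rate (default 3%); amounts exactly at the reference
age are undiscounted.  Life-years are a continuous flow integrated against
the same discount kernel.  NMB(strategy) = WTP x QALY gained per person -
net cost per person, with QALY gained measured against no screening on the
same cohort (common random numbers).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .nathist import ENTRY_AGE, STAGE_EARLY, STAGE_LATE
from .screening import StrategyOutcome


@dataclass(frozen=True)
class EconParams:
    """Economic assumptions (2021 USD).

    Treatment costs are a lumped per-stage cost at diagnosis plus a terminal
    care cost at CRC death — a stand-in for phase-based costing that
    preserves the treatment-cost offset of prevention.  Disutility defaults
    are documented placeholders: noninvasive tests carry none (and blood and
    stool tests carry the same, i.e. no differential), colonoscopy one
    quality-adjusted day, CRC care a lumped QALY decrement at diagnosis.
    """

    discount_rate: float = 0.03
    reference_age: float = ENTRY_AGE
    wtp: float = 100_000.0
    treatment_cost_by_stage: dict[str, float] = field(default_factory=lambda: {
        STAGE_EARLY: 55_000.0, STAGE_LATE: 160_000.0})
    terminal_care_cost: float = 75_000.0
    disutility_colonoscopy_days: float = 1.0
    disutility_crc_care_qaly: float = 0.20
    currency_year: int = 2021

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.wtp <= 0:
            raise ConfigurationError("wtp must be > 0")
        if any(c < 0 for c in self.treatment_cost_by_stage.values()):
            raise ConfigurationError("treatment_cost_by_stage must be >= 0")
        if self.terminal_care_cost < 0:
            raise ConfigurationError("terminal_care_cost must be >= 0")
        if self.disutility_colonoscopy_days < 0 or self.disutility_crc_care_qaly < 0:
            raise ConfigurationError("disutilities must be >= 0")


def discounted_value(amount: float, event_age: float, econ: EconParams) -> float:
    """Present value at the reference age of an amount incurred at event_age."""
    if event_age < econ.reference_age:
        raise ConfigurationError(
            f"event_age {event_age} precedes reference age {econ.reference_age}")
    return amount / (1.0 + econ.discount_rate) ** (event_age - econ.reference_age)


def discounted_life_years(death_age: float, econ: EconParams) -> float:
    """Integral of the discount kernel over [reference_age, death_age]."""
    t = max(death_age - econ.reference_age, 0.0)
    r = econ.discount_rate
    if r == 0:
        return t
    k = math.log1p(r)
    return (1.0 - math.exp(-k * t)) / k


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-strategy outcomes: events per 1000 persons, LYG/QALYG per 1000 vs
    no screening (discounted), and per-person discounted costs."""

    strategy: str
    crc_cases_per_1000: float
    crc_deaths_per_1000: float
    lyg_per_1000: float
    qalyg_per_1000: float
    total_cost_per_person: float
    net_cost_per_person: float

    @property
    def qalyg_per_person(self) -> float:
        return self.qalyg_per_1000 / 1000.0


def _person_totals(outcome: StrategyOutcome, econ: EconParams):
    n = outcome.n
    ly = np.empty(n)
    qaly = np.empty(n)
    cost = np.empty(n)
    for i, po in enumerate(outcome.person_outcomes):
        disc_ly = discounted_life_years(po.death_age, econ)
        dec = sum(discounted_value(d, a, econ) for a, d in po.disutilities)
        c = sum(discounted_value(v, a, econ) for a, v in po.costs)
        ly[i] = disc_ly
        qaly[i] = disc_ly - dec
        cost[i] = c
    return ly, qaly, cost


def summarize_outcomes(strategy_outcome: StrategyOutcome,
                       no_screen_outcome: StrategyOutcome,
                       econ: EconParams | None = None) -> OutcomeSummary:
    """Discounted LYG/QALYG per 1000 and costs vs no screening (same cohort)."""
    econ = econ or EconParams()
    econ.validate()
    if (strategy_outcome.cohort_seed != no_screen_outcome.cohort_seed
            or strategy_outcome.n != no_screen_outcome.n):
        raise ConfigurationError(
            "summarize_outcomes: strategy and no-screening outcomes must come "
            "from the same cohort and seed (common random numbers)")
    ly_s, qaly_s, cost_s = _person_totals(strategy_outcome, econ)
    ly_0, qaly_0, cost_0 = _person_totals(no_screen_outcome, econ)
    n = strategy_outcome.n
    return OutcomeSummary(
        strategy=strategy_outcome.strategy.name,
        crc_cases_per_1000=strategy_outcome.crc_cases_per_1000(),
        crc_deaths_per_1000=strategy_outcome.crc_deaths_per_1000(),
        lyg_per_1000=1000.0 * float(np.mean(ly_s) - np.mean(ly_0)),
        qalyg_per_1000=1000.0 * float(np.mean(qaly_s) - np.mean(qaly_0)),
        total_cost_per_person=float(np.mean(cost_s)),
        net_cost_per_person=float(np.mean(cost_s) - np.mean(cost_0)),
    )


def net_monetary_benefit(summary: OutcomeSummary,
                         econ: EconParams | None = None) -> float:
    """NMB = WTP x QALY gained per person - net cost per person."""
    econ = econ or EconParams()
    return econ.wtp * summary.qalyg_per_person - summary.net_cost_per_person


STATUS_DOMINATED = "dominated"
STATUS_EXTENDED = "extended_dominated"
STATUS_EFFICIENT = "efficient"


@dataclass
class FrontierResult:
    """Dominance status, ICERs between consecutive efficient strategies, and
    NMB for a set of strategy summaries."""

    summaries: list[OutcomeSummary]          # ordered by qalyg
    status: dict[str, str]
    icer: dict[str, Optional[float]]         # None for the least effective efficient
    nmb: dict[str, float]
    ties: list[tuple[str, str]] = field(default_factory=list)

    @property
    def efficient(self) -> list[str]:
        return [s.strategy for s in self.summaries
                if self.status[s.strategy] == STATUS_EFFICIENT]

    def best_by_nmb(self) -> str:
        return max(self.summaries, key=lambda s: self.nmb[s.strategy]).strategy


def compute_frontier(summaries: Sequence[OutcomeSummary],
                     econ: EconParams | None = None,
                     effect: str = "qalyg") -> FrontierResult:
    """Strict + extended dominance and ICERs.

    Strategies are sorted by the effect measure (QALY gained by default;
    ``effect="lyg"`` reports ICERs per life-year gained instead).  A strategy
    is dominated if another offers >= effect at <= cost with at least one
    strict; extended-dominated strategies (whose ICER exceeds that of the
    next more effective efficient strategy) are removed iteratively and
    ICERs recomputed.  The least effective non-dominated strategy carries no
    ICER.
    """
    econ = econ or EconParams()
    if len(summaries) < 2:
        raise ConfigurationError("compute_frontier needs at least 2 strategies")
    if effect not in ("qalyg", "lyg"):
        raise ConfigurationError("effect must be 'qalyg' or 'lyg'")
    if effect == "lyg":
        summaries = [dataclasses.replace(s, qalyg_per_1000=s.lyg_per_1000)
                     for s in summaries]
    ordered = sorted(summaries,
                     key=lambda s: (s.qalyg_per_person, s.net_cost_per_person,
                                    s.strategy))
    status: dict[str, str] = {}
    ties: list[tuple[str, str]] = []
    for i, s in enumerate(ordered):
        dominated = False
        for j, t in enumerate(ordered):
            if i == j:
                continue
            ge_q = t.qalyg_per_person >= s.qalyg_per_person
            le_c = t.net_cost_per_person <= s.net_cost_per_person
            strict = (t.qalyg_per_person > s.qalyg_per_person
                      or t.net_cost_per_person < s.net_cost_per_person)
            if ge_q and le_c and strict:
                dominated = True
                break
            if (j < i and t.qalyg_per_person == s.qalyg_per_person
                    and t.net_cost_per_person == s.net_cost_per_person):
                # exact tie: keep the first in name order, flag it
                dominated = True
                ties.append((t.strategy, s.strategy))
                break
        status[s.strategy] = STATUS_DOMINATED if dominated else STATUS_EFFICIENT

    def consecutive_icers(names: list[str]) -> list[float]:
        by_name = {s.strategy: s for s in ordered}
        out = []
        for a, b in zip(names, names[1:]):
            dq = by_name[b].qalyg_per_person - by_name[a].qalyg_per_person
            dc = by_name[b].net_cost_per_person - by_name[a].net_cost_per_person
            out.append(dc / dq if dq > 0 else math.inf)
        return out

    frontier = [s.strategy for s in ordered
                if status[s.strategy] == STATUS_EFFICIENT]
    while len(frontier) >= 3:
        icers = consecutive_icers(frontier)
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                status[frontier[k + 1]] = STATUS_EXTENDED
                frontier.pop(k + 1)
                removed = True
                break
        if not removed:
            break

    icer: dict[str, Optional[float]] = {s.strategy: None for s in ordered}
    if len(frontier) >= 2:
        for name, value in zip(frontier[1:], consecutive_icers(frontier)):
            icer[name] = value

    nmb = {s.strategy: net_monetary_benefit(s, econ) for s in ordered}
    return FrontierResult(ordered, status, icer, nmb, ties)


# ---------------------------------------------------------------------------
# table writers

def summaries_to_frame(summaries: Sequence[OutcomeSummary],
                       frontier: Optional[FrontierResult] = None) -> pd.DataFrame:
    """One row per strategy in the printed-table column order."""
    rows = []
    for s in summaries:
        row = {
            "strategy": s.strategy,
            "crc_cases_per_1000": round(s.crc_cases_per_1000, 1),
            "crc_deaths_per_1000": round(s.crc_deaths_per_1000, 1),
            "lyg_per_1000": round(s.lyg_per_1000, 1),
            "qalyg_per_1000": round(s.qalyg_per_1000, 1),
            "cost_per_person": round(s.total_cost_per_person, 2),
            "net_cost_per_person": round(s.net_cost_per_person, 2),
        }
        if frontier is not None:
            row["nmb_per_person"] = round(frontier.nmb[s.strategy], 2)
            row["status"] = frontier.status[s.strategy]
            icer = frontier.icer[s.strategy]
            row["icer_per_qalyg"] = (round(icer, 2)
                                     if icer is not None and math.isfinite(icer)
                                     else "")
        rows.append(row)
    return pd.DataFrame(rows)
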