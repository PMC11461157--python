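"""Screening-strategy overlay on natural histories.

Applies a regimen — scheduled noninvasive tests or primary colonoscopy,
follow-up colonoscopy after a positive, polypectomy, surveillance, the
resume-in-10-years rule after a negative workup — to each screening-free
life history, producing modified life courses, discounted outcomes, and an
event log.

Noninvasive tests are person-level: positivity depends on the MOST advanced
lesion present (CRC sensitivity for preclinical cancer, advanced-adenoma
sensitivity for advanced adenomas, 1 - specificity otherwise).  A positive in
a person harbouring any lesion is a true positive: a false positive occurs
only when the follow-up colonoscopy finds nothing.  Colonoscopy is
lesion-level: every lesion present is detected independently; detected
adenomas are removed and their future progression cancelled.

All overlay draws are keyed by (cohort seed, person, event type, exam age,
lesion), never by strategy: two strategies reaching the same exam see the
same uniforms (common random numbers), so contrasts between strategies are
pathwise paired and a test with zero sensitivity and perfect specificity
reproduces the unscreened life course exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .nathist import (
    ENTRY_AGE, Cohort, LesionSnapshot, NatHistParams, PersonHistory,
    STATE_ADV, STATE_CLIN, STATE_NONADV, STATE_NONE, STATE_PRECLIN,
    cancer_outcome, lesion_state_at,
)
from .rng import EV_COLO_COMPLICATION, EV_COLO_LESION, EV_SCREEN, age_key, keyed_uniform

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# profiles and strategies

@dataclass(frozen=True)
class TestProfile:
    """A screening test's accuracy, cost and per-administration disutility.

    ``sens_nonadv_adenoma=None`` (the noninvasive default) means a person
    whose most advanced lesion is a non-advanced adenoma tests positive with
    probability ``1 - specificity``.
    """

    __test__ = False  # not a test case despite the Test* name

    name: str
    modality: str  # stool | blood | colonoscopy
    sens_crc: float
    sens_adv_adenoma: float
    specificity: float
    sens_nonadv_adenoma: Optional[float] = None
    sensitivity_level: str = "person"
    unit_cost: float = 0.0
    disutility_days: float = 0.0

    def validate(self) -> None:
        for f in ("sens_crc", "sens_adv_adenoma", "specificity"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{self.name}.{f} must lie in [0, 1]")
        if self.modality == "colonoscopy" and self.sensitivity_level != "lesion":
            raise ConfigurationError(f"{self.name}: colonoscopy must be lesion-level")
        if self.modality in ("stool", "blood") and self.sensitivity_level != "person":
            raise ConfigurationError(f"{self.name}: noninvasive tests are person-level")


@dataclass(frozen=True)
class ColonoscopyProfile:
    """Lesion-level colonoscopy characteristics, costs, and complications."""

    lesion_sens_adenoma: float = 0.91
    lesion_sens_crc: float = 0.91
    specificity: float = 1.0
    cost_without_removal: float = 963.95
    cost_with_removal: float = 1312.36
    complication_prob: float = 0.0025
    complication_cost: float = 9000.0
    complication_disutility_days: float = 14.0

    def validate(self) -> None:
        for f in ("lesion_sens_adenoma", "lesion_sens_crc", "specificity",
                  "complication_prob"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ConfigurationError(f"colonoscopy.{f} must lie in [0, 1]")
        if self.cost_with_removal < self.cost_without_removal:
            raise ConfigurationError(
                "colonoscopy.cost_with_removal must be >= cost_without_removal")


@dataclass(frozen=True)
class SurveillancePolicy:
    """Post-polypectomy colonoscopy surveillance until ``stop_age``.

    Findings classes: ``high_risk`` (>=1 advanced adenoma or >=3 adenomas),
    ``low_risk`` (1-2 non-advanced).  A negative surveillance exam schedules
    the next at ``negative_interval`` years.
    """

    high_risk_interval: float = 3.0
    low_risk_interval: float = 7.0
    negative_interval: float = 10.0
    stop_age: float = 85.0

    def interval_for(self, findings: str) -> float:
        return {"high_risk": self.high_risk_interval,
                "low_risk": self.low_risk_interval}.get(findings,
                                                        self.negative_interval)

    def validate(self) -> None:
        for f in ("high_risk_interval", "low_risk_interval", "negative_interval"):
            if getattr(self, f) < 1:
                raise ConfigurationError(f"surveillance.{f} must be >= 1 year")


@dataclass(frozen=True)
class Strategy:
    """A screening regimen: a primary test repeated at ``interval`` years from
    ``start_age`` to ``stop_age``, with follow-up colonoscopy and surveillance.

    ``primary_test=None`` encodes the no-screening comparator.
    """

    name: str
    primary_test: Optional[TestProfile]
    interval: float = math.inf
    start_age: float = 45.0
    stop_age: float = 75.0
    surveillance: SurveillancePolicy = SurveillancePolicy()
    resume_after_negative_followup: float = 10.0

    def validate(self) -> None:
        if self.primary_test is not None:
            self.primary_test.validate()
            if self.interval < 1:
                raise ConfigurationError(f"{self.name}: interval must be >= 1 year")
        if self.start_age >= self.stop_age:
            raise ConfigurationError(f"{self.name}: start_age must precede stop_age")
        if self.surveillance.stop_age < self.stop_age:
            raise ConfigurationError(
                f"{self.name}: surveillance stop_age must be >= strategy stop_age")
        self.surveillance.validate()


# shipped comparator profiles (FIT accuracy from published modeling inputs;
# FIT specificity and disutilities are documented placeholders)
FIT_PROFILE = TestProfile(
    name="FIT", modality="stool", sens_crc=0.738, sens_adv_adenoma=0.238,
    specificity=0.964, unit_cost=23.42)
COLONOSCOPY_TEST = TestProfile(
    name="colonoscopy", modality="colonoscopy", sens_crc=0.91,
    sens_adv_adenoma=0.91, specificity=1.0, sensitivity_level="lesion")


def blood_test(sens_crc: float = 0.74, sens_adv_adenoma: float = 0.10,
               specificity: float = 0.90, unit_cost: float = 500.0,
               name: Optional[str] = None) -> TestProfile:
    return TestProfile(
        name=name or f"blood_crc{sens_crc:g}_aa{sens_adv_adenoma:g}_c{unit_cost:g}",
        modality="blood", sens_crc=sens_crc, sens_adv_adenoma=sens_adv_adenoma,
        specificity=specificity, unit_cost=unit_cost)


def no_screening() -> Strategy:
    return Strategy(name="no_screening", primary_test=None)


def fit_annual() -> Strategy:
    return Strategy(name="FIT_1y", primary_test=FIT_PROFILE, interval=1.0)


def colonoscopy_10y() -> Strategy:
    return Strategy(name="colonoscopy_10y", primary_test=COLONOSCOPY_TEST,
                    interval=10.0)


def blood_strategy(sens_crc: float = 0.74, sens_adv_adenoma: float = 0.10,
                   interval: float = 3.0, unit_cost: float = 500.0,
                   specificity: float = 0.90,
                   name: Optional[str] = None) -> Strategy:
    test = blood_test(sens_crc, sens_adv_adenoma, specificity, unit_cost)
    return Strategy(name=name or f"{test.name}_{interval:g}y",
                    primary_test=test, interval=interval)


# ---------------------------------------------------------------------------
# single events

def screening_test_outcome(snapshot: LesionSnapshot, profile: TestProfile,
                           u: float) -> tuple[bool, str]:
    """Person-level noninvasive test result for the most advanced lesion.

    Returns ``(positive, classification)`` with classification one of
    ``true_pos_crc``, ``true_pos_adv_adenoma``, ``true_pos_adenoma``,
    ``false_pos``, ``true_neg``, ``false_neg_crc``, ``false_neg_adv_adenoma``,
    ``false_neg_adenoma``.
    """
    if profile.sensitivity_level != "person":
        raise ConfigurationError(f"{profile.name}: person-level test required")
    state = snapshot.state
    if state == STATE_CLIN:
        raise RuntimeError("clinical CRC must preempt screening (logic error)")
    if state == STATE_PRECLIN:
        p, pos_cls, neg_cls = profile.sens_crc, "true_pos_crc", "false_neg_crc"
    elif state == STATE_ADV:
        p, pos_cls, neg_cls = (profile.sens_adv_adenoma,
                               "true_pos_adv_adenoma", "false_neg_adv_adenoma")
    elif state == STATE_NONADV:
        p = (profile.sens_nonadv_adenoma if profile.sens_nonadv_adenoma is not None
             else 1.0 - profile.specificity)
        pos_cls, neg_cls = "true_pos_adenoma", "false_neg_adenoma"
    else:
        p, pos_cls, neg_cls = 1.0 - profile.specificity, "false_pos", "true_neg"
    positive = u < p
    return positive, (pos_cls if positive else neg_cls)


@dataclass
class ColonoscopyResult:
    detected_adenoma_ids: list[int]
    detected_crc_ids: list[int]
    removal: bool
    crc_found: bool
    complication: bool
    cost: float
    findings: str  # high_risk | low_risk | none


def perform_colonoscopy(person: PersonHistory, age: float,
                        removed_ids: set[int], profile: ColonoscopyProfile,
                        seed: int) -> ColonoscopyResult:
    """Lesion-level exam: each lesion present is detected independently.

    Detected adenomas are appended to ``removed_ids`` (polypectomy cancels
    their future progression).  Detected preclinical cancers set
    ``crc_found``; their management is the caller's job.
    """
    adenomas: list[int] = []
    cancers: list[int] = []
    ak = age_key(age)
    for lesion in person.lesions:
        if lesion.id in removed_ids:
            continue
        state = lesion.state_at(age)
        if state == STATE_NONE:
            continue
        u = keyed_uniform(seed, EV_COLO_LESION, person.person_id, ak, lesion.id)
        if state == STATE_PRECLIN or state == STATE_CLIN:
            if u < profile.lesion_sens_crc:
                cancers.append(lesion.id)
        elif u < profile.lesion_sens_adenoma:
            adenomas.append(lesion.id)
    n_adv = sum(1 for lesion in person.lesions
                if lesion.id in adenomas and lesion.state_at(age) == STATE_ADV)
    removal = bool(adenomas)
    removed_ids.update(adenomas)
    if n_adv >= 1 or len(adenomas) >= 3:
        findings = "high_risk"
    elif adenomas:
        findings = "low_risk"
    else:
        findings = "none"
    u_c = keyed_uniform(seed, EV_COLO_COMPLICATION, person.person_id, ak)
    complication = u_c < profile.complication_prob
    cost = profile.cost_with_removal if removal else profile.cost_without_removal
    return ColonoscopyResult(adenomas, cancers, removal, bool(cancers),
                             complication, cost, findings)


def next_due(strategy: Strategy, mode: str, last_exam_age: float,
             last_findings: str) -> Optional[float]:
    """Age of the next scheduled exam, or ``None`` when the regimen ends.

    ``mode`` is ``routine`` or ``surveillance``; ``last_findings`` is the
    findings class of the last exam (``high_risk``/``low_risk``/``none``) or
    ``false_positive_workup`` for a clean colonoscopy after a positive
    noninvasive test (which resumes the routine regimen 10 years later).
    """
    if strategy.primary_test is None:
        return None
    if mode == "surveillance":
        nxt = last_exam_age + strategy.surveillance.interval_for(last_findings)
        return nxt if nxt <= strategy.surveillance.stop_age else None
    step = (strategy.resume_after_negative_followup
            if last_findings == "false_positive_workup" else strategy.interval)
    nxt = last_exam_age + step
    return nxt if nxt <= strategy.stop_age else None


# ---------------------------------------------------------------------------
# whole-life simulation under a strategy

@dataclass
class EventRecord:
    person_id: int
    age: float
    event: str
    detail: str = ""


@dataclass
class PersonOutcome:
    death_age: float
    crc_case: bool = False
    crc_death: bool = False
    stage: Optional[str] = None
    diagnosis_age: Optional[float] = None
    diagnosis_mode: Optional[str] = None  # screen | clinical
    # (age, amount) cost items and (age, qaly_decrement) disutility items
    costs: list[tuple[float, float]] = field(default_factory=list)
    disutilities: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class StrategyOutcome:
    """Per-person modified life courses for one strategy on one cohort."""

    strategy: Strategy
    cohort_seed: int
    n: int
    person_outcomes: list[PersonOutcome]
    events: list[EventRecord]

    def crc_deaths_per_1000(self) -> float:
        return 1000.0 * sum(p.crc_death for p in self.person_outcomes) / self.n

    def crc_cases_per_1000(self) -> float:
        return 1000.0 * sum(p.crc_case for p in self.person_outcomes) / self.n


def _first_clinical_age(person: PersonHistory, removed: set[int]) -> Optional[float]:
    ages = [l.clinical_age for l in person.lesions
            if l.clinical_age is not None and l.id not in removed]
    return min(ages) if ages else None


def _diagnose(person: PersonHistory, age: float, mode: str,
              params: NatHistParams, out: PersonOutcome,
              econ, colo: ColonoscopyProfile,
              events: Optional[list[EventRecord]]) -> None:
    stage, crc_death = cancer_outcome(person, age, mode, params)
    out.crc_case = True
    out.stage = stage
    out.diagnosis_age = age
    out.diagnosis_mode = mode
    if mode == "clinical":
        # symptom-detected CRC incurs one diagnostic colonoscopy
        out.costs.append((age, colo.cost_without_removal))
    out.costs.append((age, econ.treatment_cost_by_stage[stage]))
    out.disutilities.append((age, econ.disutility_crc_care_qaly))
    if events is not None:
        events.append(EventRecord(person.person_id, age,
                                  "crc_diagnosis_screen" if mode == "screen"
                                  else "crc_diagnosis_clinical", stage))
    oc = person.other_cause_death_age
    if crc_death is not None and crc_death < oc:
        out.crc_death = True
        out.death_age = crc_death
        out.costs.append((crc_death, econ.terminal_care_cost))
        if events is not None:
            events.append(EventRecord(person.person_id, crc_death, "crc_death", stage))
    else:
        out.death_age = oc


def _simulate_person(person: PersonHistory, strategy: Strategy,
                     colo: ColonoscopyProfile, econ, params: NatHistParams,
                     seed: int, events: Optional[list[EventRecord]]) -> PersonOutcome:
    out = PersonOutcome(death_age=person.other_cause_death_age)
    removed: set[int] = set()
    mode = "routine"
    test = strategy.primary_test
    next_exam = strategy.start_age if (test is not None and
                                       math.isfinite(strategy.interval)) else None
    oc = person.other_cause_death_age
    pid = person.person_id

    def add_colo_effects(age: float, res: ColonoscopyResult, kind: str) -> None:
        out.costs.append((age, res.cost))
        out.disutilities.append(
            (age, econ.disutility_colonoscopy_days / DAYS_PER_YEAR))
        if events is not None:
            events.append(EventRecord(pid, age, kind, res.findings))
            if res.removal:
                events.append(EventRecord(pid, age, "polypectomy",
                                          f"n={len(res.detected_adenoma_ids)}"))
        if res.complication:
            out.costs.append((age, colo.complication_cost))
            out.disutilities.append(
                (age, colo.complication_disutility_days / DAYS_PER_YEAR))
            if events is not None:
                events.append(EventRecord(pid, age, "complication", kind))

    while next_exam is not None:
        clin = _first_clinical_age(person, removed)
        if clin is not None and clin < oc and clin <= next_exam:
            _diagnose(person, clin, "clinical", params, out, econ, colo, events)
            return out
        if next_exam >= oc:
            break
        age = next_exam
        if test.sensitivity_level == "lesion" or mode == "surveillance":
            # primary or surveillance colonoscopy
            res = perform_colonoscopy(person, age, removed, colo, seed)
            kind = ("surveillance_colonoscopy" if mode == "surveillance"
                    else "screen_test")
            add_colo_effects(age, res, kind)
            if res.crc_found:
                _diagnose(person, age, "screen", params, out, econ, colo, events)
                return out
            if res.removal:
                mode = "surveillance"
                next_exam = next_due(strategy, mode, age, res.findings)
            else:
                next_exam = next_due(strategy, mode, age, "none")
        else:
            # noninvasive screen
            snap = lesion_state_at(person, age, removed)
            u = keyed_uniform(seed, EV_SCREEN, pid, age_key(age))
            positive, cls = screening_test_outcome(snap, test, u)
            out.costs.append((age, test.unit_cost))
            if test.disutility_days:
                out.disutilities.append((age, test.disutility_days / DAYS_PER_YEAR))
            if events is not None:
                events.append(EventRecord(pid, age, "screen_test",
                                          f"{test.name}:{cls}"))
            if positive:
                res = perform_colonoscopy(person, age, removed, colo, seed)
                add_colo_effects(age, res, "followup_colonoscopy")
                if res.crc_found:
                    _diagnose(person, age, "screen", params, out, econ, colo, events)
                    return out
                if res.removal:
                    mode = "surveillance"
                    next_exam = next_due(strategy, mode, age, res.findings)
                else:
                    next_exam = next_due(strategy, mode, age,
                                         "false_positive_workup")
            else:
                next_exam = next_due(strategy, mode, age, "none")

    # regimen over (or never started): any remaining clinical cancer surfaces
    clin = _first_clinical_age(person, removed)
    if clin is not None and clin < oc:
        _diagnose(person, clin, "clinical", params, out, econ, colo, events)
        return out
    out.death_age = oc
    if events is not None:
        events.append(EventRecord(pid, oc, "other_death"))
    return out


def run_strategy(cohort: Cohort, strategy: Strategy,
                 colo: ColonoscopyProfile | None = None,
                 econ=None, collect_events: bool = True) -> StrategyOutcome:
    """Apply a strategy to every person in the cohort.

    Natural histories are shared across strategies (common random numbers);
    overlay draws are keyed by (cohort seed, person, event, age).
    """
    from .cea import EconParams  # avoid import cycle at module load
    colo = colo or ColonoscopyProfile()
    econ = econ or EconParams()
    strategy.validate()
    colo.validate()
    events: Optional[list[EventRecord]] = [] if collect_events else None
    outcomes = [
        _simulate_person(p, strategy, colo, econ, cohort.params,
                         cohort.seed, events)
        for p in cohort.persons
    ]
    return StrategyOutcome(strategy, cohort.seed, cohort.n, outcomes,
                           events if events is not None else [])
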