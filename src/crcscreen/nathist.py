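"""Synthetic adenoma–carcinoma natural history.

One configurable stand-in model generates screening-free life histories with
the structure a CRC-screening cost-effectiveness analysis assumes:

* heterogeneous adenoma risk — a person-level lognormal frailty multiplies a
  non-homogeneous Poisson onset process whose cumulative hazard grows as a
  power of age;
* each adenoma independently dwells in a non-advanced state, may become
  advanced (>= 10 mm, represented categorically), may then progress to a
  preclinical (screen-detectable, asymptomatic) cancer, and after a sojourn
  time surfaces clinically;
* stage at detection is drawn from a two-stage (early/late) distribution that
  is earlier for screen detection than for symptomatic detection — the stage
  shift is screening's mortality benefit for detected cancers;
* stage-dependent CRC survival competes with other-cause mortality from a
  life table.

Event ages are continuous (real-valued years).  Every person's draws come
from named substreams keyed by (seed, person), so cohorts are extensible and
histories are independent of cohort size.  The three person-level cancer
uniforms (stage, death indicator, survival time) are stored on the history so
the screening overlay can re-evaluate stage and survival under a different
detection mode while staying perfectly paired with the unscreened path.

Average-risk cohort: persons whose history would produce a symptomatic CRC
diagnosis before age 45 are resampled (rejection within the person's own
substream), matching a screening cohort entered at 45 with no CRC history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .lifetable import DEFAULT_LIFE_TABLE, LifeTable
from .rng import STREAM_NATHIST, keyed_generator

ENTRY_AGE = 45.0

STATE_NONE = "none"
STATE_NONADV = "nonadvanced_adenoma"
STATE_ADV = "advanced_adenoma"
STATE_PRECLIN = "preclinical_crc"
STATE_CLIN = "clinical_crc"
STATE_ORDER = {STATE_NONE: 0, STATE_NONADV: 1, STATE_ADV: 2,
               STATE_PRECLIN: 3, STATE_CLIN: 4}

STAGE_EARLY = "early"
STAGE_LATE = "late"


@dataclass(frozen=True)
class StageSurvival:
    """CRC survival after detection in one stage: cure fraction + exponential."""

    prob_crc_death: float
    mean_years_to_death: float


@dataclass(frozen=True)
class NatHistParams:
    """Parameters of the stand-in adenoma–carcinoma model.

    ``baseline_onset_rate`` is the expected lifetime (to ``max_age``) adenoma
    count for a frailty-1 person; the cumulative onset hazard is
    ``rate * frailty * (age / max_age) ** onset_age_shape``.  Dwell and
    sojourn times are lognormal ``(meanlog, sdlog)`` in years.  The default
    numbers are the shipped calibration: they put unscreened lifetime CRC
    deaths for a cohort of 45-year-olds inside the 32–36 per 1000 envelope
    (see docs/methods.md).
    """

    adenoma_risk_dispersion: float = 1.1
    baseline_onset_rate: float = 1.96
    onset_age_shape: float = 2.6
    dwell_nonadv_to_adv: tuple[float, float] = (math.log(25.0), 0.7)
    prob_adv_progression: float = 0.40
    dwell_adv_to_preclinical: tuple[float, float] = (math.log(11.0), 0.8)
    sojourn_time: tuple[float, float] = (math.log(4.0), 0.5)
    stage_fractions_clinical: tuple[float, float] = (0.42, 0.58)
    stage_fractions_screen: tuple[float, float] = (0.78, 0.22)
    crc_survival: dict[str, StageSurvival] = field(default_factory=lambda: {
        STAGE_EARLY: StageSurvival(0.15, 6.0),
        STAGE_LATE: StageSurvival(0.78, 2.2),
    })
    max_age: float = 100.0

    def validate(self) -> None:
        if self.adenoma_risk_dispersion <= 0:
            raise ConfigurationError("adenoma_risk_dispersion must be > 0")
        if self.baseline_onset_rate < 0:
            raise ConfigurationError("baseline_onset_rate must be >= 0")
        if self.onset_age_shape <= 0:
            raise ConfigurationError("onset_age_shape must be > 0")
        for name in ("dwell_nonadv_to_adv", "dwell_adv_to_preclinical",
                     "sojourn_time"):
            _, sd = getattr(self, name)
            if sd < 0:
                raise ConfigurationError(f"{name}: sdlog must be >= 0")
        if not 0.0 <= self.prob_adv_progression <= 1.0:
            raise ConfigurationError("prob_adv_progression must lie in [0, 1]")
        for name in ("stage_fractions_clinical", "stage_fractions_screen"):
            fr = getattr(self, name)
            if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be nonnegative and sum to 1")
        # screen-detected stage distribution must be stochastically earlier
        if self.stage_fractions_screen[0] < self.stage_fractions_clinical[0]:
            raise ConfigurationError(
                "stage_fractions_screen: early-stage fraction must be >= clinical")
        for stage, sv in self.crc_survival.items():
            if not 0.0 <= sv.prob_crc_death <= 1.0:
                raise ConfigurationError(f"crc_survival[{stage}].prob_crc_death in [0,1]")
            if sv.mean_years_to_death <= 0:
                raise ConfigurationError(f"crc_survival[{stage}].mean_years_to_death > 0")
        if self.max_age <= ENTRY_AGE:
            raise ConfigurationError("max_age must exceed cohort entry age 45")


@dataclass
class Lesion:
    """One adenoma's event ages; ``None`` marks a transition never made."""

    id: int
    onset_age: float
    adv_age: Optional[float] = None
    preclin_age: Optional[float] = None
    clinical_age: Optional[float] = None

    def state_at(self, age: float) -> str:
        if age < self.onset_age:
            return STATE_NONE
        if self.clinical_age is not None and age >= self.clinical_age:
            return STATE_CLIN
        if self.preclin_age is not None and age >= self.preclin_age:
            return STATE_PRECLIN
        if self.adv_age is not None and age >= self.adv_age:
            return STATE_ADV
        return STATE_NONADV


@dataclass
class PersonHistory:
    """A complete screening-free life: lesions, cancer path, competing death."""

    person_id: int
    other_cause_death_age: float
    lesions: list[Lesion]
    first_clinical_crc_age: Optional[float]
    stage_at_clinical: Optional[str]
    crc_death_age_unscreened: Optional[float]
    # person-level cancer uniforms, reused by the screening overlay so stage
    # and survival stay pathwise paired across detection modes
    u_stage: float = 0.0
    u_death: float = 0.0
    u_survival: float = 0.0

    @property
    def death_age_unscreened(self) -> float:
        if self.crc_death_age_unscreened is not None:
            return min(self.crc_death_age_unscreened, self.other_cause_death_age)
        return self.other_cause_death_age


@dataclass(frozen=True)
class LesionSnapshot:
    """Most advanced lesion category present at an age, with per-state counts."""

    age: float
    state: str
    counts: dict[str, int]


def cancer_outcome(person: PersonHistory, detection_age: float, mode: str,
                   params: NatHistParams) -> tuple[str, Optional[float]]:
    """Stage at detection and CRC death age (None if cured or never dies).

    ``mode`` is ``"screen"`` or ``"clinical"``.  Uses the person's stored
    cancer uniforms: the same draw maps to a weakly earlier stage under screen
    detection, and to a weakly longer survival in the earlier stage, so
    screen detection never worsens the cancer path for a given person.
    """
    fr = (params.stage_fractions_screen if mode == "screen"
          else params.stage_fractions_clinical)
    stage = STAGE_EARLY if person.u_stage < fr[0] else STAGE_LATE
    sv = params.crc_survival[stage]
    if person.u_death < sv.prob_crc_death:
        t = -sv.mean_years_to_death * math.log(1.0 - person.u_survival)
        return stage, detection_age + t
    return stage, None


def _sample_lesions(params: NatHistParams, rng: np.random.Generator) -> list[Lesion]:
    sigma = params.adenoma_risk_dispersion
    frailty = math.exp(rng.normal(-0.5 * sigma * sigma, sigma))
    lam = params.baseline_onset_rate * frailty
    n = int(rng.poisson(lam)) if lam > 0 else 0
    lesions: list[Lesion] = []
    if n == 0:
        return lesions
    k = params.onset_age_shape
    onsets = np.sort(params.max_age * rng.random(n) ** (1.0 / k))
    mu1, sd1 = params.dwell_nonadv_to_adv
    mu2, sd2 = params.dwell_adv_to_preclinical
    mus, sds = params.sojourn_time
    for i, onset in enumerate(onsets):
        lesion = Lesion(id=i, onset_age=float(onset))
        d1 = math.exp(rng.normal(mu1, sd1)) if sd1 > 0 else math.exp(mu1)
        adv = onset + d1
        if adv < params.max_age:
            lesion.adv_age = float(adv)
            if rng.random() < params.prob_adv_progression:
                d2 = math.exp(rng.normal(mu2, sd2)) if sd2 > 0 else math.exp(mu2)
                pre = adv + d2
                if pre < params.max_age:
                    lesion.preclin_age = float(pre)
                    s = math.exp(rng.normal(mus, sds)) if sds > 0 else math.exp(mus)
                    lesion.clinical_age = float(pre + s)
        lesions.append(lesion)
    return lesions


def sample_person(params: NatHistParams, life_table: LifeTable,
                  rng: np.random.Generator, person_id: int = 0) -> PersonHistory:
    """Draw one complete screening-free history from a per-person substream."""
    params.validate()
    while True:
        u_stage, u_death, u_survival = rng.random(3)
        oc_death = life_table.sample_death_age(int(ENTRY_AGE), rng.random())
        lesions = _sample_lesions(params, rng)
        clin_ages = [l.clinical_age for l in lesions if l.clinical_age is not None]
        first_clin = min(clin_ages) if clin_ages else None
        if first_clin is not None and first_clin < ENTRY_AGE:
            continue  # average-risk cohort: no symptomatic CRC before entry
        break

    person = PersonHistory(
        person_id=person_id,
        other_cause_death_age=oc_death,
        lesions=lesions,
        first_clinical_crc_age=None,
        stage_at_clinical=None,
        crc_death_age_unscreened=None,
        u_stage=float(u_stage), u_death=float(u_death), u_survival=float(u_survival),
    )
    if first_clin is not None and first_clin < oc_death:
        person.first_clinical_crc_age = first_clin
        stage, crc_death = cancer_outcome(person, first_clin, "clinical", params)
        person.stage_at_clinical = stage
        if crc_death is not None and crc_death < oc_death:
            person.crc_death_age_unscreened = crc_death
    return person


@dataclass
class Cohort:
    """Simulated persons plus the inputs needed to replay their substreams."""

    persons: list[PersonHistory]
    params: NatHistParams
    life_table: LifeTable
    seed: int

    @property
    def n(self) -> int:
        return len(self.persons)


def simulate_cohort(params: NatHistParams, life_table: LifeTable,
                    n: int, seed: int) -> Cohort:
    """Simulate ``n`` independent screening-free histories.

    Person ``i`` is drawn from substream (seed, i), so a cohort of size 100 is
    a prefix of the cohort of size 1000 at the same seed.
    """
    if n < 1:
        raise ConfigurationError("cohort size n must be >= 1")
    params.validate()
    persons = [
        sample_person(params, life_table,
                      keyed_generator(seed, STREAM_NATHIST, pid), pid)
        for pid in range(n)
    ]
    return Cohort(persons, params, life_table, seed)


def lesion_state_at(person: PersonHistory, age: float,
                    removed_ids: frozenset | set = frozenset()) -> LesionSnapshot:
    """Most advanced lesion category at ``age``, ignoring excised lesions."""
    counts = {STATE_NONADV: 0, STATE_ADV: 0, STATE_PRECLIN: 0, STATE_CLIN: 0}
    best = STATE_NONE
    for lesion in person.lesions:
        if lesion.id in removed_ids:
            continue
        s = lesion.state_at(age)
        if s == STATE_NONE:
            continue
        counts[s] += 1
        if STATE_ORDER[s] > STATE_ORDER[best]:
            best = s
    return LesionSnapshot(age=age, state=best, counts=counts)


def crc_deaths_per_1000(cohort: Cohort) -> float:
    deaths = sum(1 for p in cohort.persons if p.crc_death_age_unscreened is not None)
    return 1000.0 * deaths / cohort.n


def crc_cases_per_1000(cohort: Cohort) -> float:
    cases = sum(1 for p in cohort.persons if p.first_clinical_crc_age is not None)
    return 1000.0 * cases / cohort.n


def calibrate_defaults(target_deaths_per_1000: tuple[float, float],
                       params0: NatHistParams, n: int, seed: int,
                       life_table: LifeTable = DEFAULT_LIFE_TABLE,
                       max_iter: int = 40) -> NatHistParams:
    """Scale ``baseline_onset_rate`` by bisection until unscreened lifetime CRC
    deaths per 1000 (at this ``n`` and ``seed``) land in the target interval.

    Deterministic given the inputs.  Raises :class:`CalibrationError` with the
    best value found if the bracket cannot reach the target.
    """
    lo_t, hi_t = target_deaths_per_1000
    if lo_t > hi_t:
        raise ConfigurationError("calibration target interval is empty")
    params0.validate()

    def deaths_at(mult: float) -> float:
        p = replace(params0, baseline_onset_rate=params0.baseline_onset_rate * mult)
        return crc_deaths_per_1000(simulate_cohort(p, life_table, n, seed))

    v0 = deaths_at(1.0)
    if lo_t <= v0 <= hi_t:
        return params0
    best_v, best_m = v0, 1.0
    # extend the bracket geometrically until it straddles the target
    if v0 > hi_t:
        lo_m, hi_m, v = 1.0, 1.0, v0
        while lo_m > 2.0 ** -40 and v > hi_t:
            lo_m /= 8.0
            v = deaths_at(lo_m)
        if lo_t <= v <= hi_t:
            return replace(params0,
                           baseline_onset_rate=params0.baseline_onset_rate * lo_m)
        if v > hi_t:
            raise CalibrationError(
                f"calibration failed: bracket exhausted, best deaths per 1000 "
                f"= {v:.2f}", best_value=v)
    else:
        lo_m, hi_m, v = 1.0, 1.0, v0
        while hi_m < 2.0 ** 9 and v < lo_t:
            hi_m *= 8.0
            v = deaths_at(hi_m)
        if lo_t <= v <= hi_t:
            return replace(params0,
                           baseline_onset_rate=params0.baseline_onset_rate * hi_m)
        if v < lo_t:
            raise CalibrationError(
                f"calibration failed: bracket exhausted, best deaths per 1000 "
                f"= {v:.2f}", best_value=v)
    for _ in range(max_iter):
        mid = math.sqrt(lo_m * hi_m)
        v = deaths_at(mid)
        if abs(v - 0.5 * (lo_t + hi_t)) < abs(best_v - 0.5 * (lo_t + hi_t)):
            best_v, best_m = v, mid
        if lo_t <= v <= hi_t:
            return replace(params0,
                           baseline_onset_rate=params0.baseline_onset_rate * mid)
        if v > hi_t:
            hi_m = mid
        else:
            lo_m = mid
        if hi_m / lo_m < 1.0 + 1e-6:
            break
    raise CalibrationError(
        f"calibration failed: best deaths per 1000 = {best_v:.2f} at "
        f"onset-rate multiplier {best_m:.4f}", best_value=best_v)


#: The shipped default calibration.
DEFAULT_NATHIST = NatHistParams()
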