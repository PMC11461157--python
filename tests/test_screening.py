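import math
from dataclasses import replace

import numpy as np
import pytest

from crcscreen.cea import EconParams, summarize_outcomes
from crcscreen.errors import ConfigurationError
from crcscreen.nathist import (DEFAULT_NATHIST, Lesion, LesionSnapshot,
                               PersonHistory, STATE_ADV, STATE_NONADV,
                               STATE_NONE, STATE_PRECLIN, crc_deaths_per_1000,
                               simulate_cohort)
from crcscreen.screening import (ColonoscopyProfile, Strategy, TestProfile,
                                 blood_strategy, blood_test, colonoscopy_10y,
                                 fit_annual, next_due, no_screening,
                                 perform_colonoscopy, run_strategy,
                                 screening_test_outcome)


def _snapshot(state, age=60.0):
    return LesionSnapshot(age=age, state=state, counts={})


def _person(lesions, oc=95.0, pid=0):
    return PersonHistory(person_id=pid, other_cause_death_age=oc,
                         lesions=lesions, first_clinical_crc_age=None,
                         stage_at_clinical=None, crc_death_age_unscreened=None)


# ---------------------------------------------------------------------------
# noninvasive test outcome

@pytest.mark.parametrize("state,expected_p,pos_cls", [
    (STATE_PRECLIN, 0.74, "true_pos_crc"),
    (STATE_ADV, 0.10, "true_pos_adv_adenoma"),
    (STATE_NONE, 0.10, "false_pos"),
    (STATE_NONADV, 0.10, "true_pos_adenoma"),
])
def test_positivity_probability_matches_profile(state, expected_p, pos_cls):
    """Person-level positivity: CRC sensitivity for preclinical cancer, AA
    sensitivity for advanced adenomas, 1 - specificity otherwise; a positive
    with any lesion present is not a false positive."""
    profile = blood_test(0.74, 0.10, 0.90, 500.0)
    rng = np.random.default_rng(42)
    n = 10_000
    hits = 0
    for u in rng.random(n):
        positive, cls = screening_test_outcome(_snapshot(state), profile, u)
        if positive:
            hits += 1
            assert cls == pos_cls
    se = math.sqrt(expected_p * (1 - expected_p) / n)
    assert abs(hits / n - expected_p) < 4 * se


def test_perfect_specificity_never_flags_nonadvanced():
    profile = blood_test(0.74, 0.10, specificity=1.0)
    for u in np.linspace(0.0, 0.999, 50):
        positive, _ = screening_test_outcome(_snapshot(STATE_NONADV), profile, u)
        assert not positive


def test_clinical_state_at_screen_is_a_logic_error():
    profile = blood_test()
    with pytest.raises(RuntimeError, match="clinical"):
        screening_test_outcome(_snapshot("clinical_crc"), profile, 0.5)


def test_lesion_level_profile_rejected_for_person_level_outcome():
    from crcscreen.screening import COLONOSCOPY_TEST
    with pytest.raises(ConfigurationError):
        screening_test_outcome(_snapshot(STATE_NONE), COLONOSCOPY_TEST, 0.5)


# ---------------------------------------------------------------------------
# colonoscopy

def test_colonoscopy_perfect_sensitivity_removes_all_adenomas():
    person = _person([Lesion(0, 50.0), Lesion(1, 52.0)])
    profile = ColonoscopyProfile(lesion_sens_adenoma=1.0, lesion_sens_crc=1.0)
    removed = set()
    res = perform_colonoscopy(person, 60.0, removed, profile, seed=1)
    assert sorted(res.detected_adenoma_ids) == [0, 1]
    assert removed == {0, 1} and res.removal
    assert res.cost == 1312.36
    assert res.findings == "low_risk"


def test_colonoscopy_without_findings_costs_less():
    person = _person([])
    res = perform_colonoscopy(person, 60.0, set(), ColonoscopyProfile(), seed=1)
    assert not res.removal and res.cost == 963.95 and res.findings == "none"


def test_colonoscopy_zero_sensitivity_detects_nothing():
    person = _person([Lesion(0, 50.0), Lesion(1, 52.0, adv_age=55.0)])
    profile = ColonoscopyProfile(lesion_sens_adenoma=0.0, lesion_sens_crc=0.0)
    res = perform_colonoscopy(person, 60.0, set(), profile, seed=1)
    assert not res.detected_adenoma_ids and not res.crc_found


def test_advanced_or_many_adenomas_classified_high_risk():
    person = _person([Lesion(0, 50.0, adv_age=55.0)])
    profile = ColonoscopyProfile(lesion_sens_adenoma=1.0)
    res = perform_colonoscopy(person, 60.0, set(), profile, seed=1)
    assert res.findings == "high_risk"
    person3 = _person([Lesion(i, 50.0) for i in range(3)])
    res3 = perform_colonoscopy(person3, 60.0, set(), profile, seed=1)
    assert res3.findings == "high_risk"


# ---------------------------------------------------------------------------
# next_due state machine

def test_negative_followup_resumes_routine_ten_years_later():
    strat = blood_strategy()
    assert next_due(strat, "routine", 52.0, "false_positive_workup") == 62.0


def test_high_risk_surveillance_interval_is_three_years():
    strat = blood_strategy()
    assert next_due(strat, "surveillance", 60.0, "high_risk") == 63.0
    assert next_due(strat, "surveillance", 60.0, "low_risk") == 67.0


def test_surveillance_stops_at_85():
    strat = blood_strategy()
    assert next_due(strat, "surveillance", 84.0, "high_risk") is None
    assert next_due(strat, "surveillance", 82.0, "high_risk") == 85.0


def test_routine_screens_stop_at_75():
    strat = blood_strategy(interval=3.0)
    assert next_due(strat, "routine", 72.0, "none") == 75.0
    assert next_due(strat, "routine", 74.0, "none") is None


# ---------------------------------------------------------------------------
# run_strategy

def test_inert_test_reproduces_no_screening_exactly(small_cohort, econ):
    """Zero sensitivity + perfect specificity: same life courses as no
    screening under common random numbers; only test costs differ."""
    inert = Strategy(name="inert", interval=1.0, primary_test=TestProfile(
        name="inert", modality="blood", sens_crc=0.0, sens_adv_adenoma=0.0,
        specificity=1.0, unit_cost=50.0))
    ns = run_strategy(small_cohort, no_screening(), econ=econ,
                      collect_events=False)
    io = run_strategy(small_cohort, inert, econ=econ, collect_events=False)
    for a, b in zip(ns.person_outcomes, io.person_outcomes):
        assert a.death_age == b.death_age
        assert a.crc_death == b.crc_death and a.crc_case == b.crc_case
        assert a.stage == b.stage
    assert io.crc_deaths_per_1000() == ns.crc_deaths_per_1000()


def test_inert_test_cost_matches_annuity_oracle(small_cohort, econ):
    """Net cost of an inert annual test equals the discounted annuity of its
    unit cost over the simulated survivor curve."""
    cost = 50.0
    inert = Strategy(name="inert", interval=1.0, primary_test=TestProfile(
        name="inert", modality="blood", sens_crc=0.0, sens_adv_adenoma=0.0,
        specificity=1.0, unit_cost=cost))
    ns = run_strategy(small_cohort, no_screening(), econ=econ,
                      collect_events=False)
    io = run_strategy(small_cohort, inert, econ=econ, collect_events=False)
    summary = summarize_outcomes(io, ns, econ)
    # screening stops at symptomatic diagnosis, so the annuity runs to the
    # earlier of death and clinical diagnosis
    stops = np.array([min(p.death_age,
                          p.diagnosis_age if p.diagnosis_age is not None
                          else math.inf)
                      for p in ns.person_outcomes])
    expected = np.mean([
        sum(cost / 1.03 ** (a - 45.0) for a in np.arange(45.0, 76.0)
            if a < d)
        for d in stops])
    assert summary.net_cost_per_person == pytest.approx(expected, rel=1e-9)
    assert summary.lyg_per_1000 == pytest.approx(0.0, abs=1e-9)


def test_no_screening_matches_nathist_unscreened_deaths(small_cohort):
    ns = run_strategy(small_cohort, no_screening(), collect_events=False)
    assert ns.crc_deaths_per_1000() == crc_deaths_per_1000(small_cohort)


def test_perfect_annual_colonoscopy_prevents_all_clinical_cancer(life_table):
    """With degenerate 4-year dwell/sojourn stages (all > the 1-year exam
    interval), perfect lesion sensitivity and exams to age 99, every lesion is
    excised or screen-detected before it can surface clinically."""
    params = replace(DEFAULT_NATHIST,
                     dwell_nonadv_to_adv=(math.log(4.0), 0.0),
                     prob_adv_progression=1.0,
                     dwell_adv_to_preclinical=(math.log(4.0), 0.0),
                     sojourn_time=(math.log(4.0), 0.0))
    cohort = simulate_cohort(params, life_table, 500, seed=21)
    from crcscreen.screening import COLONOSCOPY_TEST, SurveillancePolicy
    strat = Strategy(name="perfect_colo", primary_test=COLONOSCOPY_TEST,
                     interval=1.0, stop_age=99.0,
                     surveillance=SurveillancePolicy(stop_age=99.0))
    colo = ColonoscopyProfile(lesion_sens_adenoma=1.0, lesion_sens_crc=1.0)
    out = run_strategy(cohort, strat, colo=colo, collect_events=False)
    assert all(p.diagnosis_mode != "clinical" for p in out.person_outcomes)


def test_screening_never_increases_cohort_crc_deaths(small_cohort):
    ns = run_strategy(small_cohort, no_screening(), collect_events=False)
    for strat in (fit_annual(), colonoscopy_10y(), blood_strategy()):
        out = run_strategy(small_cohort, strat, collect_events=False)
        assert out.crc_deaths_per_1000() <= ns.crc_deaths_per_1000()


def test_event_log_conservation_and_ordering(small_cohort):
    """Every positive noninvasive test gets exactly one follow-up colonoscopy;
    events per person are age-ordered; none occur after death or windows."""
    out = run_strategy(small_cohort, blood_strategy(), collect_events=True)
    by_person: dict[int, list] = {}
    for e in out.events:
        by_person.setdefault(e.person_id, []).append(e)
    positives = followups = 0
    for pid, events in by_person.items():
        ages = [e.age for e in events]
        assert ages == sorted(ages)
        death = out.person_outcomes[pid].death_age
        for e in events:
            assert e.age <= death
            if e.event == "screen_test":
                assert e.age <= 75.0
                if "pos" in e.detail and "false_neg" not in e.detail:
                    positives += 1
            elif e.event == "followup_colonoscopy":
                followups += 1
            elif e.event == "surveillance_colonoscopy":
                assert e.age <= 85.0
    assert positives == followups


def test_costs_are_nonnegative_and_sum(small_cohort, econ):
    out = run_strategy(small_cohort, fit_annual(), econ=econ,
                       collect_events=False)
    for p in out.person_outcomes:
        assert all(v >= 0 for _, v in p.costs)
        assert all(d >= 0 for _, d in p.disutilities)


def test_shorter_interval_weakly_increases_qalyg_and_costs(small_cohort, econ):
    ns = run_strategy(small_cohort, no_screening(), econ=econ,
                      collect_events=False)
    prev_q, prev_c = -math.inf, math.inf
    for interval in (3.0, 2.0, 1.0):
        out = run_strategy(small_cohort, blood_strategy(interval=interval),
                           econ=econ, collect_events=False)
        s = summarize_outcomes(out, ns, econ)
        assert s.qalyg_per_1000 >= prev_q
        assert s.total_cost_per_person > prev_c or prev_c == math.inf
        prev_q, prev_c = s.qalyg_per_1000, s.total_cost_per_person


def test_strategy_validation_errors():
    with pytest.raises(ConfigurationError, match="interval"):
        blood_strategy(interval=0.5).validate()
    with pytest.raises(ConfigurationError):
        TestProfile(name="bad", modality="blood", sens_crc=1.2,
                    sens_adv_adenoma=0.1, specificity=0.9).validate()
    with pytest.raises(ConfigurationError):
        ColonoscopyProfile(cost_with_removal=100.0).validate()
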