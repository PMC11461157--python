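import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

from crcscreen.cea import (EconParams, OutcomeSummary, STATUS_DOMINATED,
                           STATUS_EFFICIENT, STATUS_EXTENDED, compute_frontier,
                           discounted_life_years, discounted_value,
                           net_monetary_benefit, summaries_to_frame,
                           summarize_outcomes)
from crcscreen.errors import ConfigurationError
from crcscreen.screening import no_screening, fit_annual, run_strategy


def _summary(name, qalyg_pp, net_cost):
    return OutcomeSummary(strategy=name, crc_cases_per_1000=0.0,
                          crc_deaths_per_1000=0.0, lyg_per_1000=qalyg_pp * 1000,
                          qalyg_per_1000=qalyg_pp * 1000,
                          total_cost_per_person=net_cost,
                          net_cost_per_person=net_cost)


# ---------------------------------------------------------------------------
# discounting

def test_discounting_closed_form_examples(econ):
    assert discounted_value(100.0, 45.0, econ) == 100.0
    assert discounted_value(100.0, 55.0, econ) == pytest.approx(
        100.0 / 1.03 ** 10)
    r0 = EconParams(discount_rate=0.0)
    assert discounted_value(100.0, 55.0, r0) == 100.0


def test_discounting_matches_formula_on_random_triples():
    rng = np.random.default_rng(7)
    for _ in range(100):
        amount = float(rng.uniform(1, 1e5))
        age = float(rng.uniform(45, 100))
        r = float(rng.uniform(0, 0.1))
        econ = EconParams(discount_rate=r)
        assert discounted_value(amount, age, econ) == pytest.approx(
            amount / (1 + r) ** (age - 45), rel=1e-12)


def test_discounting_before_reference_age_errors(econ):
    with pytest.raises(ConfigurationError):
        discounted_value(1.0, 40.0, econ)


def test_discounted_life_years_integrates_kernel(econ):
    """Closed-form annuity equals numerical integration of (1+r)^-t."""
    t = 23.7
    grid = np.linspace(0, t, 200_001)
    numeric = np.trapezoid(1.03 ** -grid, grid)
    assert discounted_life_years(45.0 + t, econ) == pytest.approx(
        numeric, rel=1e-8)
    assert discounted_life_years(45.0 + t, EconParams(discount_rate=0.0)) == \
        pytest.approx(t, rel=1e-12)


# ---------------------------------------------------------------------------
# summaries and NMB

def test_self_comparison_yields_zero_gains(small_cohort, econ):
    ns = run_strategy(small_cohort, no_screening(), econ=econ,
                      collect_events=False)
    s = summarize_outcomes(ns, ns, econ)
    assert s.lyg_per_1000 == 0.0 and s.qalyg_per_1000 == 0.0
    assert s.net_cost_per_person == 0.0


def test_mismatched_cohorts_rejected(small_cohort, mid_cohort, econ):
    a = run_strategy(small_cohort, no_screening(), collect_events=False)
    b = run_strategy(mid_cohort, no_screening(), collect_events=False)
    with pytest.raises(ConfigurationError):
        summarize_outcomes(a, b, econ)


def test_fit_reduces_crc_deaths_below_no_screening(small_cohort, econ):
    ns = run_strategy(small_cohort, no_screening(), econ=econ,
                      collect_events=False)
    fit = run_strategy(small_cohort, fit_annual(), econ=econ,
                       collect_events=False)
    s = summarize_outcomes(fit, ns, econ)
    assert s.crc_deaths_per_1000 < ns.crc_deaths_per_1000()


def test_qalyg_equals_lyg_without_disutilities(small_cohort):
    from crcscreen.screening import ColonoscopyProfile
    econ0 = EconParams(disutility_colonoscopy_days=0.0,
                       disutility_crc_care_qaly=0.0)
    colo0 = ColonoscopyProfile(complication_disutility_days=0.0)
    ns = run_strategy(small_cohort, no_screening(), colo=colo0, econ=econ0,
                      collect_events=False)
    fit = run_strategy(small_cohort, fit_annual(), colo=colo0, econ=econ0,
                       collect_events=False)
    s = summarize_outcomes(fit, ns, econ0)
    assert s.qalyg_per_1000 == pytest.approx(s.lyg_per_1000, abs=1e-9)


def test_qalyg_below_lyg_with_screening_disutilities(small_cohort):
    """With decrements attached only to screening activity (tests,
    colonoscopies, complications), quality adjustment can only lower the
    gains: QALYG <= LYG.  The CRC-care decrement is zeroed because averting
    diagnoses would otherwise add quality-of-life gains on top of life-years.
    """
    econ_s = EconParams(disutility_crc_care_qaly=0.0)
    ns = run_strategy(small_cohort, no_screening(), econ=econ_s,
                      collect_events=False)
    fit = run_strategy(small_cohort, fit_annual(), econ=econ_s,
                       collect_events=False)
    s = summarize_outcomes(fit, ns, econ_s)
    assert s.qalyg_per_1000 <= s.lyg_per_1000


def test_raising_discount_rate_weakly_reduces_gains(small_cohort):
    summaries = {}
    for r in (0.0, 0.03, 0.05):
        econ_r = EconParams(discount_rate=r)
        ns = run_strategy(small_cohort, no_screening(), econ=econ_r,
                          collect_events=False)
        fit = run_strategy(small_cohort, fit_annual(), econ=econ_r,
                           collect_events=False)
        summaries[r] = summarize_outcomes(fit, ns, econ_r)
    assert summaries[0.0].qalyg_per_1000 >= summaries[0.03].qalyg_per_1000
    assert summaries[0.03].qalyg_per_1000 >= summaries[0.05].qalyg_per_1000


def test_nmb_formula(econ):
    s = _summary("s", 0.1, 2000.0)
    assert net_monetary_benefit(s, econ) == pytest.approx(8000.0)
    zero = _summary("z", 0.0, 0.0)
    assert net_monetary_benefit(zero, econ) == 0.0
    saving = _summary("c", 0.05, -500.0)
    assert net_monetary_benefit(saving, econ) > econ.wtp * 0.05


# ---------------------------------------------------------------------------
# frontier

def test_frontier_hand_worked_strict_dominance(econ):
    """No screening, A(0.10, $1000), B(0.12, $5000), C(0.11, $6000):
    C dominated; ICER(A vs no screening) = $10,000; ICER(B vs A) = $200,000."""
    summaries = [_summary("no_screen", 0.0, 0.0), _summary("A", 0.10, 1000.0),
                 _summary("B", 0.12, 5000.0), _summary("C", 0.11, 6000.0)]
    fr = compute_frontier(summaries, econ)
    assert fr.status["C"] == STATUS_DOMINATED
    assert fr.status["A"] == fr.status["B"] == STATUS_EFFICIENT
    assert fr.icer["no_screen"] is None
    assert fr.icer["A"] == pytest.approx(10_000.0)
    assert fr.icer["B"] == pytest.approx(200_000.0)


def test_frontier_hand_worked_extended_dominance(econ):
    """A(0.10, $1000), B(0.15, $4000), C(0.20, $5000): B extended dominated
    (ICER B->C $20k < ICER A->B $60k); final ICER(C vs A) = $40,000."""
    summaries = [_summary("A", 0.10, 1000.0), _summary("B", 0.15, 4000.0),
                 _summary("C", 0.20, 5000.0)]
    fr = compute_frontier(summaries, econ)
    assert fr.status["B"] == STATUS_EXTENDED
    assert fr.icer["C"] == pytest.approx(40_000.0)
    assert fr.icer["A"] is None


def test_cost_saving_strategy_dominates_no_screening(econ):
    fr = compute_frontier([_summary("no_screen", 0.0, 0.0),
                           _summary("saver", 0.1, -100.0)], econ)
    assert fr.status["saver"] == STATUS_EFFICIENT
    assert fr.status["no_screen"] == STATUS_DOMINATED


def _oracle_statuses(points):
    """Brute-force dominance/extended-dominance oracle.

    A strategy is dominated if some other strategy is weakly better in both
    coordinates and strictly better in one; it is extended-dominated if a
    convex combination of two other strategies is (randomizing between
    strategies is allowed on the frontier).
    """
    out = {}
    for name, (q, c) in points.items():
        others = {k: v for k, v in points.items() if k != name}
        if any(q2 >= q and c2 <= c and (q2 > q or c2 < c)
               for q2, c2 in others.values()):
            out[name] = STATUS_DOMINATED
            continue
        extended = False
        for (qa, ca), (qb, cb) in itertools.combinations(others.values(), 2):
            if qa > qb:
                (qa, ca), (qb, cb) = (qb, cb), (qa, ca)
            if qa <= q <= qb and qb > qa:
                lam = (qb - q) / (qb - qa)
                c_mix = lam * ca + (1 - lam) * cb
                if c_mix < c:
                    extended = True
                    break
        out[name] = STATUS_EXTENDED if extended else STATUS_EFFICIENT
    return out


def test_frontier_matches_brute_force_oracle_on_random_instances(econ):
    rng = np.random.default_rng(99)
    for trial in range(300):
        k = int(rng.integers(2, 7))
        points = {f"s{i}": (float(rng.uniform(0, 0.2)),
                            float(rng.uniform(-2000, 8000)))
                  for i in range(k)}
        summaries = [_summary(n, q, c) for n, (q, c) in points.items()]
        fr = compute_frontier(summaries, econ)
        oracle = _oracle_statuses(points)
        assert fr.status == oracle, f"trial {trial}: {points}"
        # efficient strategies have strictly increasing qalyg and icers
        eff = fr.efficient
        qs = [points[n][0] for n in eff]
        assert qs == sorted(qs)
        icers = [fr.icer[n] for n in eff if fr.icer[n] is not None]
        assert all(a < b for a, b in zip(icers, icers[1:]))


def test_frontier_invariant_to_input_order(econ):
    rng = np.random.default_rng(3)
    points = {f"s{i}": (float(rng.uniform(0, 0.2)), float(rng.uniform(0, 5000)))
              for i in range(6)}
    summaries = [_summary(n, q, c) for n, (q, c) in points.items()]
    fr1 = compute_frontier(summaries, econ)
    fr2 = compute_frontier(list(reversed(summaries)), econ)
    assert fr1.status == fr2.status and fr1.icer == fr2.icer


def test_max_nmb_strategy_is_efficient_and_brackets_wtp(econ):
    """The NMB-optimal strategy lies on the frontier, with its ICER below the
    willingness to pay and the next efficient strategy's ICER above it."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        k = int(rng.integers(3, 7))
        points = {f"s{i}": (float(rng.uniform(0, 0.2)),
                            float(rng.uniform(-2000, 8000)))
                  for i in range(k)}
        summaries = [_summary(n, q, c) for n, (q, c) in points.items()]
        fr = compute_frontier(summaries, econ)
        best = fr.best_by_nmb()
        assert fr.status[best] == STATUS_EFFICIENT
        eff = fr.efficient
        i = eff.index(best)
        own = fr.icer[best]
        assert own is None or own <= econ.wtp + 1e-9
        if i + 1 < len(eff):
            assert fr.icer[eff[i + 1]] >= econ.wtp - 1e-9


def test_exact_ties_flagged_and_first_kept(econ):
    summaries = [_summary("a", 0.1, 100.0), _summary("b", 0.1, 100.0),
                 _summary("z", 0.0, 0.0)]
    fr = compute_frontier(summaries, econ)
    assert ("a", "b") in fr.ties
    assert fr.status["a"] == STATUS_EFFICIENT
    assert fr.status["b"] == STATUS_DOMINATED


def test_summary_table_has_printed_precision(econ):
    summaries = [_summary("no_screen", 0.0, 0.0), _summary("A", 0.1234567, 1000.0)]
    fr = compute_frontier(summaries, econ)
    df = summaries_to_frame(summaries, fr)
    assert list(df["strategy"]) == ["no_screen", "A"]
    assert df.loc[1, "qalyg_per_1000"] == round(123.4567, 1)
    assert {"nmb_per_person", "status", "icer_per_qalyg"} <= set(df.columns)


def test_frontier_per_lyg_flag_uses_life_years(econ):
    """With effect='lyg' the frontier ranks on life-years gained."""
    a = OutcomeSummary("a", 0, 0, lyg_per_1000=100.0, qalyg_per_1000=50.0,
                       total_cost_per_person=1000.0, net_cost_per_person=1000.0)
    b = OutcomeSummary("b", 0, 0, lyg_per_1000=200.0, qalyg_per_1000=40.0,
                       total_cost_per_person=3000.0, net_cost_per_person=3000.0)
    z = _summary("z", 0.0, 0.0)
    fr_q = compute_frontier([a, b, z], econ)            # b dominated on QALYG
    assert fr_q.status["b"] == STATUS_DOMINATED
    fr_l = compute_frontier([a, b, z], econ, effect="lyg")
    assert fr_l.status["b"] == STATUS_EFFICIENT
    assert fr_l.icer["b"] == pytest.approx(2000.0 / 0.1)  # $ per LYG
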