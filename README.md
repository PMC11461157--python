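# crcscreen

**When is a blood test good enough to screen for colorectal cancer?**

Blood-based biomarker tests are an appealing alternative to stool tests and
colonoscopy for colorectal cancer (CRC) screening, and US Medicare (CMS)
will cover a triennial blood test with ≥ 74% CRC sensitivity and ≥ 90%
specificity.  But that coverage floor says nothing about *advanced adenomas*
— the precursor lesions whose removal is what actually prevents cancer — or
about price.  `crcscreen` is a microsimulation pipeline for asking, for
modellers and health economists: under what combinations of CRC sensitivity,
advanced-adenoma (AA) sensitivity, screening interval and unit cost is a
blood test as effective and as cost-effective as annual fecal immunochemical
testing (FIT) or decennial colonoscopy?

The pipeline comprises:

* `crcscreen.nathist` — a synthetic adenoma–carcinoma natural history:
  heterogeneous (frailty-driven) adenoma onset, progression non-advanced →
  advanced (≥ 10 mm) → preclinical → clinical cancer, two-stage
  stage-at-detection with stage-dependent survival, and competing
  other-cause mortality from a life table.  Calibrated so an unscreened
  cohort of 45-year-olds suffers 32–36 lifetime CRC deaths per 1000.
* `crcscreen.screening` — strategy overlay: person-level noninvasive tests,
  lesion-level colonoscopy, follow-up colonoscopy, polypectomy,
  surveillance to 85, the resume-at-10-years rule, complications.  All
  randomness is keyed per (seed, person, event), so strategies are compared
  under common random numbers.
* `crcscreen.cea` — discounting (3%/y to age 45), QALY/LY gained vs no
  screening, ICER frontier with strict + extended dominance, and net
  monetary benefit, NMB = $100,000 × QALYG per person − net cost.
* `crcscreen.threshold` — the 900-scenario full factorial over CRC
  sensitivity {74, 83, 92%} × AA sensitivity {10–50%} × interval {1–3 y} ×
  cost {$25–$500}, each classified as cost-effective iff non-dominated with
  ICER < $150,000/QALY against FIT and colonoscopy.
* `crcscreen.discovery` — scenario discovery: random-forest
  (mean-decrease-in-Gini) ranking of which test characteristics drive
  cost-effectiveness, and a locally weighted regression surface of NMB over
  the top three, with iso-NMB contours against the colonoscopy reference.

See `docs/methods.md` for the model, parameters and their defaults, and the
design decisions.

## Worked example

```python
from crcscreen import (DEFAULT_LIFE_TABLE, DEFAULT_NATHIST, simulate_cohort,
                       no_screening, fit_annual, colonoscopy_10y,
                       blood_strategy, run_strategy,
                       summarize_outcomes, compute_frontier)
from crcscreen.cea import EconParams, net_monetary_benefit

cohort = simulate_cohort(DEFAULT_NATHIST, DEFAULT_LIFE_TABLE, 20_000, seed=1)
econ = EconParams()
ns = run_strategy(cohort, no_screening(), econ=econ)
summaries = [
    summarize_outcomes(run_strategy(cohort, s, econ=econ), ns, econ)
    for s in (no_screening(), fit_annual(), colonoscopy_10y(),
              blood_strategy())          # $500 CMS-minimum blood test, 3-yearly
]
frontier = compute_frontier(summaries, econ)
for s in frontier.summaries:
    print(f"{s.strategy:28s} deaths/1000={s.crc_deaths_per_1000:5.1f} "
          f"QALYG/1000={s.qalyg_per_1000:6.1f} "
          f"NMB=${frontier.nmb[s.strategy]:8,.0f} {frontier.status[s.strategy]}")
```

prints (seed 1, n = 20,000):

```
no_screening                 deaths/1000= 33.6 QALYG/1000=   0.0 NMB=$       0 dominated
blood_crc0.74_aa0.1_c500_3y  deaths/1000= 13.8 QALYG/1000=  94.8 NMB=$   8,539 dominated
FIT_1y                       deaths/1000=  6.3 QALYG/1000= 145.1 NMB=$  17,265 efficient
colonoscopy_10y              deaths/1000=  1.4 QALYG/1000= 165.3 NMB=$  18,541 efficient
```

Reading: without screening this cohort loses 33.6 per 1000 to CRC.  A $500
triennial blood test that only meets the CMS floor (74% CRC / 10% AA
sensitivity) does help relative to nothing — but it is *dominated*: it
yields ~35% fewer QALYs than annual FIT and ~43% fewer than decennial
colonoscopy while costing more, and forfeits roughly half of colonoscopy's
net monetary benefit.  FIT is cost-saving (negative net cost) and
colonoscopy buys its extra QALYs at an ICER well under $100,000/QALY, so
both remain on the efficiency frontier.

The same analysis as numbered drivers:

```bash
python analysis/01_natural_history.py    # calibration check, n = 200,000
python analysis/02_base_case.py          # table above + frontier CSVs
python analysis/03_threshold_grid.py     # 900-scenario factorial
python analysis/04_scenario_discovery.py # RF importance + NMB map
```

or via the CLI: `crcscreen simulate|base-case|threshold|discovery|report
[--config config.yaml] [--seed N] [--cohort-n N] [--out DIR]`.

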