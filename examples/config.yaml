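# Example crcscreen run configuration.  Every key is optional; omitted keys
# take the shipped defaults (see docs/methods.md).
cohort_n: 20000
seed: 1
output_dir: results

natural_history:
  baseline_onset_rate: 1.96      # shipped calibration (32-36 deaths/1000)
  adenoma_risk_dispersion: 1.1
  prob_adv_progression: 0.40

econ:
  discount_rate: 0.03
  wtp: 100000.0

colonoscopy:
  lesion_sens_adenoma: 0.91
  lesion_sens_crc: 0.91
  cost_without_removal: 963.95
  cost_with_removal: 1312.36

strategies:
  - builtin: no_screening
  - builtin: fit_annual
  - builtin: colonoscopy_10y
  - name: blood_cms_3y
    interval: 3.0
    primary_test:
      name: blood_cms
      modality: blood
      sens_crc: 0.74
      sens_adv_adenoma: 0.10
      specificity: 0.90
      unit_cost: 500.0

scenario_spec:
  crc_sens_levels: [0.74, 0.83, 0.92]
  aa_sens_levels: [0.10, 0.20, 0.30, 0.40, 0.50]
  intervals: [1.0, 2.0, 3.0]
  costs: [25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 175.0, 200.0, 225.0, 250.0,
          275.0, 300.0, 325.0, 350.0, 375.0, 400.0, 425.0, 450.0, 475.0, 500.0]
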