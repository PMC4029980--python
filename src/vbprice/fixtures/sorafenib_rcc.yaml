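# Sorafenib vs best supportive care, second-line metastatic renal cell cancer.
# Monthly-cycle Markov cohort cost-utility model, payer perspective, euro 2012.
#
# Transition entries written as {mean, n} are expanded at load time into
# beta(mean*n, (1-mean)*n) pseudo-count distributions, preserving the stated
# point probability as the beta mean (n = per-arm trial sample size).
name: sorafenib-rcc-second-line
cycle_length_months: 1
horizon_cycles: 120          # ten years of monthly cycles
cohort_size: 1000
discount_annual: 0.035
wtp_thresholds: [20000, 40000, 60000]   # 1x / 2x / 3x GDP per capita (~20,517), rounded
psa:
  iterations: 50000
  seed: 20140503

utilities:
  pfs: {dist: beta, params: [153.26, 48.4]}   # mean 0.76, s.e. 0.03
  pd:  {dist: beta, params: [91.8, 43.2]}     # mean 0.68, s.e. 0.04

arms:
  - name: sorafenib
    role: intervention
    transitions:
      pfs_to_pd:    {mean: 0.104, n: 451}
      pfs_to_death: {mean: 0.034, n: 451}
      pd_to_death:  {mean: 0.050, n: 451}
    costs:
      pfs_monthly:      {dist: gamma, params: [1714, 4.8]}   # mean ~357
      pd_early_monthly: {dist: gamma, params: [7196, 4.8]}   # mean ~1499, PD months 1-2
      pd_late_monthly:  {dist: gamma, params: [3696, 4.8]}   # mean ~770, PD month 3+
      drug_monthly:     {dist: uniform, params: [2880, 2900]}  # current reference price
  - name: bsc
    role: comparator
    transitions:
      pfs_to_pd:    {mean: 0.210, n: 452}
      pfs_to_death: {mean: 0.042, n: 452}
      pd_to_death:  {mean: 0.051, n: 452}
    costs:
      pfs_monthly:      {dist: gamma, params: [1336, 4.8]}   # mean ~278
      pd_early_monthly: {dist: gamma, params: [3696, 4.8]}   # mean ~770
      pd_late_monthly:  {dist: gamma, params: [3696, 4.8]}

trial:
  n_intervention: 451
  n_comparator: 452
  median_pfs_intervention: 5.5
  median_pfs_comparator: 2.8
  median_os_intervention: 17.8
  median_os_comparator: 15.2
  hr_pfs: [0.51, 0.43, 0.60]
  hr_os: [0.72, 0.54, 0.94]

# Resource-use provenance behind the cost-distribution means (metadata only;
# the gamma/uniform specs above are the authoritative model inputs).
provenance:
  currency: "euro, 2012 price lists"
  pfs_resource_use:
    sorafenib: "1 specialist visit e40; CT e256 every 3 months; hypertension management 3 visits e60/year (folded into the e357 PFS mean)"
    bsc: "1 GP + 2 nurses + 1 psychologist e70; CT e256 every 6 months"
    shared: "daily hospitalisation e135; blood panel (FBC, SGPT/SGOT, creatinine) e157"
  pd_resource_use:
    consultation: "1 GP + 2 nurses + 1 psychologist e70"
    analgesia: "opioids (fentanyl patches 5.4-19/unit, morphine 0.07-0.36/unit), ondansetron 0.66/unit"
  drug_price_note: "uniform spread 2880-2900 reflects the fixed administrative spread on the monthly acquisition price at recommended full dose"
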