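discount_rate: 0.03
exchange_rate: 70.42
price_year: 2020
daly:
  per_case_ure: 0.02
  per_case_cataract: 0.85
  duration_ure: 3.0
  duration_cataract: 19.9
  discount_rate: 0.03
  mode: lifetime_total
psa:
  n_sims: 10000
  distribution: gamma
  dispersion: 0.25
  dispersion_by_category: {}
  vary_outcomes: false
  shared_provider_shock: 0.0
unit_costs:
  spectacle: 3.5
  surgery: 70.0
  patient_access_per_surgery: 20.0
lambda_grid:
- 0.0
- 25.0
- 50.0
- 75.0
- 100.0
- 125.0
- 150.0
- 175.0
- 200.0
- 225.0
- 250.0
- 275.0
- 300.0
- 325.0
- 350.0
- 375.0
- 400.0
- 425.0
- 450.0
- 475.0
- 500.0
- 525.0
- 550.0
- 575.0
- 600.0
- 625.0
- 650.0
- 675.0
- 700.0
- 725.0
- 750.0
- 775.0
- 800.0
- 825.0
- 850.0
- 875.0
- 900.0
- 925.0
- 950.0
- 975.0
- 1000.0
- 1025.0
- 1050.0
- 1075.0
- 1100.0
- 1125.0
- 1150.0
- 1175.0
- 1200.0
- 1225.0
- 1250.0
- 1275.0
- 1300.0
- 1325.0
- 1350.0
- 1375.0
- 1400.0
- 1425.0
- 1450.0
- 1475.0
- 1500.0
- 1525.0
- 1550.0
- 1575.0
- 1600.0
- 1625.0
- 1650.0
- 1675.0
- 1700.0
- 1725.0
- 1750.0
- 1775.0
- 1800.0
- 1825.0
- 1850.0
- 1875.0
- 1900.0
- 1925.0
- 1950.0
- 1975.0
- 2000.0
- 2025.0
- 2050.0
- 2075.0
- 2100.0
- 2125.0
- 2150.0
- 2175.0
- 2200.0
- 2225.0
- 2250.0
- 2275.0
- 2300.0
- 2325.0
- 2350.0
- 2375.0
- 2400.0
- 2425.0
- 2450.0
- 2475.0
- 2500.0
gdp_per_capita_threshold: 1928.0
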