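# Default rule configuration: five policy tracks.
#
# Conventions:
#   - shares are on the unit interval (0.10 means 10%)
#   - rates carry the units noted per condition
#   - comparisons are strict by default (">" / "<"); set `strict: false`
#     for an inclusive boundary
#
# The 0.10 cutoff on the nutrient summary exposure values is the
# theoretically anchored one (">10% of the population at risk").
# Cutoffs marked "calibrate-to-supplement" are placeholders set at
# natural breaks of the synthetic generator's default marginals and are
# expected to be re-calibrated against an authoritative per-variable
# cutoff table before use on real data. The highly-relevant tier uses
# the same formula shape at stricter cutoffs.

conditions:
  # Nutrient deficiency (summary exposure value = share of population at
  # risk of inadequate intake)
  sev_b12_high:         {indicator: sev_b12, direction: greater, cutoff: 0.10}
  sev_b12_very_high:    {indicator: sev_b12, direction: greater, cutoff: 0.25}   # calibrate-to-supplement
  sev_omega3_high:      {indicator: sev_omega3, direction: greater, cutoff: 0.10}
  sev_omega3_very_high: {indicator: sev_omega3, direction: greater, cutoff: 0.25} # calibrate-to-supplement

  # Blue food availability: domestic production or imports, kg/person/year
  bf_production_high:   {indicator: bf_production, direction: greater, cutoff: 10.0}  # calibrate-to-supplement
  bf_imports_high:      {indicator: bf_imports, direction: greater, cutoff: 10.0}     # calibrate-to-supplement

  # Terrestrial meat intake, g/person/day
  red_meat_high:        {indicator: red_meat_intake, direction: greater, cutoff: 30.0}  # calibrate-to-supplement
  red_meat_very_high:   {indicator: red_meat_intake, direction: greater, cutoff: 60.0}  # calibrate-to-supplement
  ruminant_high:        {indicator: ruminant_meat_intake, direction: greater, cutoff: 15.0}  # calibrate-to-supplement
  ruminant_very_high:   {indicator: ruminant_meat_intake, direction: greater, cutoff: 35.0}  # calibrate-to-supplement

  # Cardiovascular disease burden, DALYs per 100,000
  cvd_high:             {indicator: cvd_burden, direction: greater, cutoff: 3000.0}  # calibrate-to-supplement
  cvd_very_high:        {indicator: cvd_burden, direction: greater, cutoff: 5000.0}  # calibrate-to-supplement

  # Blue food dependence (shares) and climate hazard (score on [0,1])
  bf_employment_high:   {indicator: bf_employment_share, direction: greater, cutoff: 0.03}  # calibrate-to-supplement
  bf_export_high:       {indicator: bf_export_share, direction: greater, cutoff: 0.05}      # calibrate-to-supplement
  bf_nutrition_high:    {indicator: bf_nutrition_share, direction: greater, cutoff: 0.15}   # calibrate-to-supplement
  climate_hazard_high:      {indicator: climate_hazard, direction: greater, cutoff: 0.50}   # calibrate-to-supplement
  climate_hazard_very_high: {indicator: climate_hazard, direction: greater, cutoff: 0.75}   # calibrate-to-supplement

policies:
  - policy_id: nutrient_b12
    label: Reduce vitamin B12 deficiency through blue food consumption
    # deficiency AND availability (availability = production OR imports)
    highly_relevant:
      all:
        - sev_b12_very_high
        - any: [bf_production_high, bf_imports_high]
    relevant:
      all:
        - sev_b12_high
        - any: [bf_production_high, bf_imports_high]

  - policy_id: nutrient_omega3
    label: Reduce omega-3 (DHA/EPA) deficiency through blue food consumption
    highly_relevant:
      all:
        - sev_omega3_very_high
        - any: [bf_production_high, bf_imports_high]
    relevant:
      all:
        - sev_omega3_high
        - any: [bf_production_high, bf_imports_high]

  - policy_id: cvd_red_meat
    label: Reduce cardiovascular disease burden linked to red meat overconsumption
    # high red meat intake AND high CVD burden AND availability
    highly_relevant:
      all:
        - red_meat_very_high
        - cvd_very_high
        - any: [bf_production_high, bf_imports_high]
    relevant:
      all:
        - red_meat_high
        - cvd_high
        - any: [bf_production_high, bf_imports_high]

  - policy_id: ghg_footprint
    label: Reduce dietary greenhouse-gas footprints from ruminant meat
    highly_relevant:
      all:
        - ruminant_very_high
        - any: [bf_production_high, bf_imports_high]
    relevant:
      all:
        - ruminant_high
        - any: [bf_production_high, bf_imports_high]

  - policy_id: safeguard_climate
    label: Safeguard blue food contributions to nutrition, economies and livelihoods under climate change
    # substantial contribution (employment OR export OR nutrition) AND climate hazard
    highly_relevant:
      all:
        - any: [bf_employment_high, bf_export_high, bf_nutrition_high]
        - climate_hazard_very_high
    relevant:
      all:
        - any: [bf_employment_high, bf_export_high, bf_nutrition_high]
        - climate_hazard_high
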