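# Bundled example assessment: three trisiloxane polyether surfactants
# (spray-tank adjuvants) assessed at screening level for honey bees.
# Application rates are the cleaned California use-report maxima
# (default mode) and the total rates from an almond-orchard tunnel
# residue study (empirical mode); residues are the peak measured
# concentrations by matrix group; endpoints are the published
# laboratory toxicity values for these materials.
locs:
  acute: 0.4
  chronic: 1.0
rud: 110.0
contact_unit_dose: 2.7
chemicals:
  - chemical: trisiloxane-317
    rate: 1.42            # kg a.i./ha, cleaned use-report maximum (neat products)
    rate_unit: kg_per_ha
    empirical_rate: 2.056 # kg a.i./ha, orchard study total of two applications
    residues:
      pollen: 76.2        # mg/kg, peak forager pollen (day 0-1)
      nectar: 2.12        # mg/kg, peak forager nectar
      jelly: 0.768        # mg/kg, peak larvae (royal-jelly surrogate)
    tox:
      adult_contact_ld50: 43.67   # µg/bee, trimmed Spearman-Kärber (95% CI 37.30-51.13)
      adult_oral_ld50: 285.16     # µg/bee, trimmed Spearman-Kärber (95% CI 247.84-328.10)
      adult_chronic_noed: 85.9    # µg/bee/day, Williams vs pooled controls
      larval_acute_ld50: 100.0    # µg/bee, unbounded (> highest dose tested)
      larval_chronic_noed: 33.0   # µg/bee/day, Fisher-Holm (non-monotone data)
    greater_than: [larval_acute_ld50]
  - chemical: trisiloxane-OH
    rate: 0.404
    rate_unit: kg_per_ha
    empirical_rate: 0.380
    residues:
      pollen: 26.5
      nectar: 0.48
      jelly: 0.147
    tox:
      adult_contact_ld50: 100.0   # µg/bee, unbounded
      adult_oral_ld50: 100.0      # µg/bee, unbounded
      adult_chronic_noed: 12.8    # µg/bee/day, Williams vs pooled controls
      larval_acute_ld50: 100.0    # µg/bee, unbounded
      larval_chronic_noed: 40.0   # µg/bee/day, Cochran-Armitage step-down (monotone)
    greater_than: [adult_contact_ld50, adult_oral_ld50, larval_acute_ld50]
  - chemical: trisiloxane-acetoxy
    rate: 0.688
    rate_unit: kg_per_ha
    empirical_rate: 0.260
    residues:
      pollen: 4.53
      nectar: 0.1         # LOQ-substituted (all nectar samples censored)
      jelly: 0.1          # LOQ-substituted (all larvae samples censored)
    residues_provenance:
      nectar: loq_substituted
      jelly: loq_substituted
    tox:
      adult_contact_ld50: 150.0   # µg/bee, unbounded
      adult_oral_ld50: 304.0      # µg/bee, unbounded
      adult_chronic_noed: 94.0    # µg/bee/day, Williams vs pooled controls
      larval_acute_ld50: 100.0    # µg/bee, unbounded
      larval_chronic_noed: 33.0   # µg/bee/day, Fisher-Holm (non-monotone data)
    greater_than:
      [adult_contact_ld50, adult_oral_ld50, larval_acute_ld50]
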