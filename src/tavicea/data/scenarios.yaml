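# Bundled scenario battery, version 1.
# Overrides are dotted parameter-set paths; structural scenarios that need
# user-supplied inputs (alternative survival or clinical-input sources) are
# marked runnable: false.
schema_version: 1
scenarios:
  - id: "1"
    label: "Survival data from PARTNER 3"
    runnable: false
    note: "Requires trial-derived survival inputs supplied by the user."
  - id: "2"
    label: "No survival benefit with TAVI"
    overrides:
      modifiers.hr_death_af: 1.0
      modifiers.hr_death_stroke: 1.0
    note: >-
      Structural toggle: with both state hazard ratios at 1, survival is the
      background life-table curve in both arms.
  - id: "3"
    label: "Including AE costs within 30 days"
    overrides:
      settings.include_acute_ae_costs: true
  - id: "4"
    label: "Time horizon = 5 years"
    overrides:
      settings.horizon_years: 5
  - id: "5"
    label: "Time horizon = 10 years"
    overrides:
      settings.horizon_years: 10
  - id: "6"
    label: "Time horizon = 15 years"
    overrides:
      settings.horizon_years: 15
  - id: "7"
    label: "Time horizon = 20 years"
    overrides:
      settings.horizon_years: 20
  - id: "8"
    label: "Time horizon = 30 years"
    overrides:
      settings.horizon_years: 30
  - id: "9"
    label: "Clinical inputs for the pooled SAPIEN 3 / SAPIEN 3 Ultra sample"
    runnable: false
    note: "Requires the pooled-sample event inputs supplied by the user."
  - id: "10"
    label: "Costs and outcomes both discounted at 0%"
    overrides:
      settings.annual_discount_rate_costs: 0.0
      settings.annual_discount_rate_outcomes: 0.0
  - id: "11"
    label: "Costs and outcomes both discounted at 5%"
    overrides:
      settings.annual_discount_rate_costs: 0.05
      settings.annual_discount_rate_outcomes: 0.05
  - id: "12"
    label: "Costs discounted at 3% and outcomes at 0%"
    overrides:
      settings.annual_discount_rate_costs: 0.03
      settings.annual_discount_rate_outcomes: 0.0
  - id: "13"
    label: "RR of death with treated AF = 1"
    overrides:
      modifiers.hr_death_af: 1.0
  - id: "14"
    label: "Monthly costs associated with treated AF health state = 0"
    overrides:
      state_costs.af_month1: 0
      state_costs.af_month2plus: 0
  - id: "15"
    label: "Late POAF mortality: HR 5.1 for death with treated AF"
    overrides:
      modifiers.hr_death_af: 5.1
    note: >-
      The published hazard ratio is encoded; the late-POAF incidence inputs
      themselves are not public and remain at their base values.
  - id: "16"
    label: "KPP database procedure costs (TAVI 277,327 SEK; SAVR 243,462 SEK)"
    overrides:
      procedure.index_procedure_cost.tavi: 277327
      procedure.index_procedure_cost.savr: 243462
      procedure.rehab_rate.tavi: 0.0
      procedure.rehab_rate.savr: 0.0
      procedure.pacemaker_expected_cost_override.tavi: 0
    note: >-
      The KPP figures cover the whole intervention process, so they replace
      the index cost and the rehabilitation/pacemaker components are zeroed
      to make the per-arm totals equal the quoted values.
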