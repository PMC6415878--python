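# Default model inputs: NHS England, GBP 2017, 7-year horizon.
# Probabilities and shares are fractions (0.942, not 94.2%); the report
# layer formats percentages.

epidemiology:
  n_year1: 161657            # patients with known/suspected BE attending endoscopy, year 1
  annual_growth: 0.20        # annual increase in attending population
  horizon_years: 7
  hospital_cohort: 649       # per-hospital annual cohort (161,657 / 249)
  parasa:                    # observed disease-state counts at index endoscopy
    total: 2696
    dysplastic: 905
    lg: 751
    hg: 106
    eac: 48

accuracy:
  per_patient_sens: 0.942
  per_patient_spec: 0.944
  per_lesion_sens_nbi: 0.890
  per_lesion_spec_nbi: 0.800
  per_lesion_sens_wle: 0.791
  per_lesion_spec_wle: 0.810
  hist_sens: 1.0             # histopathology confirmation layer (off by default)
  hist_spec: 0.629
  hist_layer_enabled: false
  lesions_per_dysplastic: 1.0   # lesion multiplicity for per-lesion scenarios

procedure:
  biopsies_nbi: 3.6          # biopsies per procedure, NBI targeted
  biopsies_wle: 7.6          # biopsies per procedure, HD-WLE Seattle protocol
  endo_ae_nbi:               # per-procedure adverse-event risks, pure NBI technique
    stricture: 0.0001
    perforation: 0.014
    bleeding: 0.002
  endo_ae_wle:
    stricture: 0.0001
    perforation: 0.030
    bleeding: 0.005
  treat_ae:                  # per-treated-patient risks of EMR+RFA
    stricture: 0.335
    perforation: 0.013
    bleeding: 0.075
  eradication_rate: 0.949
  ae_exposure_basis: per_procedure

economics:
  discount_rate: 0.035
  perspective: nhs           # nhs | hospital
  market_share_nbi: 0.84     # NBI arm is a mixed arm: 84% NBI / 16% HD-WLE
  accuracy_level: per_patient  # per_patient | per_lesion
  long_term: false

costs:
  tariff_endoscopy: 517      # NHS tariff, esophageal endoscopy (FZ03A)
  tariff_emr_rfa: 2101       # NHS tariff, EMR + RFA
  cost_per_biopsy: 82
  ae_costs:
    stricture: 392
    bleeding: 392
    perforation: 2852
  cancer_cost_per_year: 7647
  staff_rates:               # GBP/hour
    admin: 23
    nurse_noncontact: 41
    consultant_ba: 142
    nurse_contact: 100
    consultant_during: 142
  staff_times_nbi:           # hours/procedure
    admin: 0.30
    nurse_noncontact: 0.42
    consultant_ba: 0.50
    nurse_contact: 0.30
    consultant_during: 0.30
  staff_times_wle:
    admin: 0.30
    nurse_noncontact: 0.89
    consultant_ba: 0.50
    nurse_contact: 0.30
    consultant_during: 0.30
  snare_pack_cost: 240
  snare_pack_size: 20
  forceps_pack_cost: 210
  forceps_pack_size: 10

equipment:
  hospitals: 249
  rooms_per_hospital: 3.25
  endoscopists_per_hospital: 3.25
  scopes_per_room: 4
  olympus_share: 0.84
  nbi_capable_share: 0.83
  hd_scope_share: 0.40
  trained_share: 0.50
  replacement_rate: 0.029
  unit_cost_system: 41316
  unit_cost_scope: 30487
  training_cost_per_day_nbi: 1136
  training_cost_per_day_wle: 795
  training_days_nbi: 2
  training_days_wle: 0
  maintenance_system_nbi: 4590
  maintenance_system_wle: 4527
  maintenance_scope_nbi: 4285
  maintenance_scope_wle: 4089
  amortization_years: 7
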