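{
  "validated": {
    "weights": {
      "severe_preeclampsia_or_eclampsia": 5,
      "congestive_heart_failure": 5,
      "pulmonary_hypertension": 4,
      "congenital_or_valvular_heart_disease": 4,
      "placenta_previa_accreta_abruption": 4,
      "ischemic_heart_disease_or_arrhythmia": 3,
      "sickle_cell_bleeding_coagulopathy_anticoagulation": 3,
      "mild_preeclampsia": 2,
      "gestational_hypertension": 2,
      "chronic_hypertension": 2,
      "multiple_gestation": 2,
      "iufd": 2,
      "autoimmune_or_lupus": 2,
      "hiv_aids": 2,
      "epilepsy_cva_neuromuscular": 2,
      "substance_abuse": 2,
      "previous_cesarean_or_myomectomy": 1,
      "chronic_renal_disease": 1,
      "asthma": 1,
      "diabetes_on_insulin": 1,
      "alcohol_abuse": 1
    },
    "age_bands": [[35, 1], [40, 2], [45, 3]],
    "bmi_bands": [[40, 2], [50, 3]]
  },
  "modified": {
    "weights": {
      "severe_preeclampsia_or_eclampsia": 5,
      "congestive_heart_failure": 5,
      "pulmonary_hypertension": 4,
      "congenital_or_valvular_heart_disease": 4,
      "placenta_previa_accreta_abruption": 4,
      "ischemic_heart_disease_or_arrhythmia": 3,
      "sickle_cell_bleeding_coagulopathy_anticoagulation": 3,
      "mild_preeclampsia": 2,
      "gestational_hypertension": 2,
      "chronic_hypertension": 2,
      "multiple_gestation": 2,
      "iufd": 2,
      "autoimmune_or_lupus": 2,
      "hiv_aids": 2,
      "epilepsy_cva_neuromuscular": 2,
      "substance_abuse": 2,
      "previous_cesarean_or_myomectomy": 1,
      "chronic_renal_disease": 1,
      "asthma": 1,
      "diabetes_on_insulin": 1,
      "alcohol_abuse": 1,
      "srom_over_48h": 2,
      "unbooked": 2
    },
    "age_bands": [[35, 1], [40, 2], [45, 3]],
    "bmi_bands": [[40, 2], [50, 3]]
  }
}
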