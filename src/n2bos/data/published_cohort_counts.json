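{
  "description": "Printed test-result counts from a published follow-up study of 61 double lung / heart-lung transplant recipients (58 after excluding three with unresolved terminal potential BOS). Used as worked examples: the operating characteristics and predictive-ability percentages are recomputed from these counts, never stored.",
  "n_recipients": 58,
  "contingency": [
    {"variable": "fev1", "dimension": "pct_baseline", "direction": "less", "cutoff": 90,
     "nobos_normal": 264, "nobos_abnormal": 28, "bos_normal": 0, "bos_abnormal": 37,
     "bos0p_normal": 0, "bos0p_abnormal": 7},
    {"variable": "fvc", "dimension": "pct_baseline", "direction": "less", "cutoff": 90,
     "nobos_normal": 276, "nobos_abnormal": 11, "bos_normal": 8, "bos_abnormal": 27,
     "bos0p_normal": 5, "bos0p_abnormal": 1},
    {"variable": "n2_slope", "dimension": "pct_baseline", "direction": "greater", "cutoff": 299,
     "nobos_normal": 240, "nobos_abnormal": 12, "bos_normal": 12, "bos_abnormal": 13,
     "bos0p_normal": 4, "bos0p_abnormal": 3},
    {"variable": "fev1", "dimension": "pct_predicted", "direction": "less", "cutoff": 49,
     "nobos_normal": 279, "nobos_abnormal": 14, "bos_normal": 12, "bos_abnormal": 24,
     "bos0p_normal": 7, "bos0p_abnormal": 0},
    {"variable": "fvc", "dimension": "pct_predicted", "direction": "less", "cutoff": 52,
     "nobos_normal": 275, "nobos_abnormal": 13, "bos_normal": 24, "bos_abnormal": 10,
     "bos0p_normal": 6, "bos0p_abnormal": 0},
    {"variable": "n2_slope", "dimension": "pct_predicted", "direction": "greater", "cutoff": 478,
     "nobos_normal": 234, "nobos_abnormal": 18, "bos_normal": 1, "bos_abnormal": 24,
     "bos0p_normal": 0, "bos0p_abnormal": 7}
  ],
  "prediction": [
    {"criterion": "fev1", "definition": "fev1 % basal < 90",
     "total_results": 299, "total_abnormal": 28, "abnormal_preceding_bos": 11},
    {"criterion": "n2_slope", "definition": "n2_slope % pred. > 478",
     "total_results": 259, "total_abnormal": 22, "abnormal_preceding_bos": 12},
    {"criterion": "combined", "definition": "fev1 % basal < 90 + n2_slope % pred. > 478",
     "total_results": 259, "total_abnormal": 12, "abnormal_preceding_bos": 9}
  ],
  "patient_outcomes": {
    "n_bos": 15,
    "n_bos_preceded_by_bos0p": 4,
    "n_never_bos": 46,
    "n_never_bos_never_bos0p": 43,
    "n_bos0p_patients": 7,
    "n_bos0p_progressed": 4
  }
}
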