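{
  "version": "sofa-standard/1.0",
  "comment": "Standard SOFA cutoff bands. Upper bounds are exclusive unless noted. Cardiovascular is simplified to MAP + a vasopressor flag (no dose data), capping that subscore at 2.",
  "respiration": {
    "pf_lower_bounds": [400, 300, 200, 100],
    "vent_required_from_score": 3
  },
  "coagulation": {
    "platelet_lower_bounds": [150, 100, 50, 20]
  },
  "liver": {
    "bilirubin_upper_bounds": [1.2, 2.0, 6.0, 12.0]
  },
  "cardiovascular": {
    "map_threshold": 70,
    "vasopressor_score": 2
  },
  "cns": {
    "gcs_lower_bounds": [15, 13, 10, 6]
  },
  "renal": {
    "creatinine_upper_bounds": [1.2, 2.0, 3.5, 5.0],
    "urine_bounds": {"lt_500": 3, "lt_200": 4}
  }
}
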