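{
  "version": "1.0",
  "description": "Published reference constants shipped for the built-in generic derivation and for comparison reports.",
  "ecottc_candidates_ng_per_l": {
    "comment": "Per-Verhaar-class fifth-percentile candidates of the log10 PNEC distribution, back-transformed; keys are Verhaar classes.",
    "1": {"empirical": 5.496, "normal": 5.587, "logistic": 5.929},
    "2": {"empirical": 9.455, "normal": 37.53, "logistic": 44.45},
    "3": {"empirical": 1.254, "normal": 2.534, "logistic": 2.982},
    "4": {"empirical": 0.134, "normal": 0.1433, "logistic": 0.1175},
    "5": {"empirical": 4.012, "normal": 5.434, "logistic": 5.750}
  },
  "cramer_ttc_ug_per_kg_day": {"1": 30.0, "2": 9.0, "3": 1.5},
  "af_ladder": [
    {"rule_id": "1-acute", "af": 10000},
    {"rule_id": "2-acute", "af": 5000},
    {"rule_id": "3-acute", "af": 1000},
    {"rule_id": "3+1-not-ms", "af": 1000},
    {"rule_id": "3+1-on-ms", "af": 100},
    {"rule_id": "3+2-incl-ms", "af": 50},
    {"rule_id": "3+3", "af": 10},
    {"rule_id": "chronic-rich", "af": [1, 5]}
  ],
  "kienzler_2019_ecottc_ng_per_l": {
    "comment": "Literature comparison values, reference only.",
    "1": 45, "2": 19, "3": 15, "4": 0.2, "5": 4
  },
  "exposure_defaults": {"bw_kg": 70.0, "bw_kg_ttc_variant": 60.0, "wu_l_per_day": 2.0, "allocation": 0.1, "risk_level": 1e-06}
}
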