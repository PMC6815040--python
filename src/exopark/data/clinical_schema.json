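{
  "schema_version": "1.0",
  "description": "Column schema for the clinical cohort table (one row per subject). Encodings are fixed here, never inferred from data.",
  "columns": {
    "subject_id": {"type": "string", "required": true},
    "group": {"type": "enum", "values": ["PD", "control"], "required": true},
    "age": {"type": "float", "required": true, "min_exclusive": 0},
    "sex": {"type": "enum", "values": ["M", "F"], "required": true},
    "handedness": {"type": "enum", "values": ["right", "left"], "required": true},
    "disease_duration": {"type": "float", "required": false, "min": 0},
    "levodopa_dose": {"type": "float", "required": false, "min": 0},
    "other_medications": {"type": "string", "required": false},
    "other_dose_mg": {"type": "string", "required": false},
    "updrs3_off": {"type": "int", "required": false, "min": 0, "max": 108},
    "updrs3_on": {"type": "int", "required": false, "min": 0, "max": 108},
    "moca": {"type": "int", "required": false, "min": 0, "max": 30}
  },
  "pd_required": ["disease_duration", "updrs3_off", "updrs3_on"]
}
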