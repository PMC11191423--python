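{
  "type": "object",
  "required": ["trial_id", "setup_kind", "sample_rate_hz", "status", "n_breaths",
               "markers", "breath_table", "heatmap_deviation", "events",
               "advisories", "decisions", "outcomes", "thresholds"],
  "properties": {
    "trial_id": {"type": "string"},
    "setup_kind": {"type": "string", "enum": ["spiroware_like", "wbreath_like"]},
    "sample_rate_hz": {"type": "number"},
    "status": {"type": "string", "enum": ["ok", "error"]},
    "error": {"type": ["string", "null"]},
    "n_breaths": {"type": "integer"},
    "markers": {
      "type": ["object", "null"],
      "required": ["washin_start", "equilibration", "washout_start", "test_end",
                   "c_start", "critical_washin", "critical_washout",
                   "incomplete_washin", "incomplete_washout", "n_breaths"],
      "properties": {
        "washin_start": {"type": ["integer", "null"]},
        "equilibration": {"type": ["integer", "null"]},
        "washout_start": {"type": ["integer", "null"]},
        "test_end": {"type": ["integer", "null"]},
        "c_start": {"type": ["number", "null"]},
        "critical_washin": {"type": ["array", "null"], "items": {"type": "integer"}},
        "critical_washout": {"type": ["array", "null"], "items": {"type": "integer"}},
        "incomplete_washin": {"type": "boolean"},
        "incomplete_washout": {"type": "boolean"},
        "n_breaths": {"type": "integer"}
      }
    },
    "breath_table": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["breath_index", "v_insp", "v_exp", "duration"],
        "properties": {
          "breath_index": {"type": "integer"},
          "v_insp": {"type": "number"},
          "v_exp": {"type": "number"},
          "duration": {"type": "number"},
          "c_et": {"type": ["number", "null"]},
          "c_insp_mean": {"type": ["number", "null"]},
          "deviation": {"type": ["number", "null"]}
        }
      }
    },
    "heatmap_deviation": {"type": "array", "items": {"type": "number"}},
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "first_breath", "last_breath", "in_critical_washin",
                     "in_critical_washout", "origin", "detail"],
        "properties": {
          "kind": {"type": "string",
                   "enum": ["sigh", "breath_hold", "leak", "irregular_breathing", "error"]},
          "first_breath": {"type": "integer"},
          "last_breath": {"type": "integer"},
          "in_critical_washin": {"type": "boolean"},
          "in_critical_washout": {"type": "boolean"},
          "origin": {"type": "string", "enum": ["auto", "manual"]},
          "detail": {"type": "string"}
        }
      }
    },
    "advisories": {
      "type": "object",
      "required": ["mm_step", "equilibration", "manual_checklist"],
      "properties": {
        "mm_step": {"type": "object"},
        "equilibration": {"type": "object"},
        "manual_checklist": {"type": "array", "items": {"type": "string"}}
      }
    },
    "decisions": {
      "type": "object",
      "properties": {
        "washin": {"type": ["object", "null"]},
        "washout": {"type": ["object", "null"]}
      }
    },
    "outcomes": {
      "type": ["object", "null"],
      "required": ["frc_ml", "cev_ml", "lci", "n_washout_breaths", "c_start", "c_end"],
      "properties": {
        "frc_ml": {"type": "number"},
        "cev_ml": {"type": "number"},
        "lci": {"type": "number"},
        "n_washout_breaths": {"type": "integer"},
        "c_start": {"type": "number"},
        "c_end": {"type": "number"}
      }
    },
    "thresholds": {"type": "object"}
  }
}
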