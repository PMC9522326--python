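{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "polyconform simulation summary",
  "type": "object",
  "required": ["config", "scheme_description", "final", "longrun"],
  "properties": {
    "config": {
      "type": "object",
      "required": ["scheme", "generations", "version"],
      "properties": {
        "scheme": {"type": "object"},
        "generations": {"type": "integer", "minimum": 1},
        "p0": {"type": ["array", "null"], "items": {"type": "number"}},
        "seed": {"type": ["integer", "null"]},
        "record": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "scheme_description": {"type": "string"},
    "final": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}},
    "longrun": {
      "type": ["object", "null"],
      "required": ["classification", "period", "cycle_points", "ergodic_mean"],
      "properties": {
        "classification": {"enum": ["fixed_point", "cycle", "nonconvergent"]},
        "period": {"type": ["integer", "null"], "minimum": 1},
        "cycle_points": {
          "type": "array",
          "items": {"type": "array", "items": {"type": "number"}}
        },
        "fixed_point": {"type": ["array", "null"], "items": {"type": "number"}},
        "ergodic_mean": {"type": ["array", "null"], "items": {"type": "number"}},
        "divergence_rate": {"type": ["number", "null"]}
      }
    }
  }
}
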