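{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fearsim experiment design",
  "description": "Declarative conditioning design: stimulus catalog, trial types, and per-group ordered stages. YAML files with the same structure are accepted as an equivalent dialect. Semantic constraints beyond this structural schema (label uniqueness, cross-references, trials-xor-delay) are enforced by fearsim.validate_design.",
  "type": "object",
  "required": ["catalog", "trials", "groups"],
  "properties": {
    "catalog": {
      "type": "object",
      "required": ["cs", "contexts"],
      "properties": {
        "cs": {"type": "array", "items": {"type": "string"}},
        "contexts": {"type": "array", "items": {"type": "string"}, "minItems": 1}
      }
    },
    "trials": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "cues": {"type": "array", "items": {"type": "string"}},
          "us": {"type": "integer", "enum": [0, 1]}
        }
      }
    },
    "groups": {
      "type": "object",
      "minProperties": 1,
      "additionalProperties": {
        "type": "array",
        "minItems": 1,
        "items": {
          "type": "object",
          "required": ["label"],
          "properties": {
            "label": {"type": "string"},
            "context": {"type": ["string", "null"]},
            "trials": {
              "type": "array",
              "items": {
                "anyOf": [
                  {"type": "string"},
                  {
                    "type": "array",
                    "prefixItems": [{"type": "string"}, {"type": "integer"}],
                    "minItems": 2,
                    "maxItems": 2
                  }
                ]
              }
            },
            "iti_steps": {"type": "integer", "minimum": 0},
            "delay_steps": {"type": "integer", "minimum": 0}
          }
        }
      }
    }
  }
}
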