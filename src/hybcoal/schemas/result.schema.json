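{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hybcoal CLI result",
  "type": "object",
  "required": ["command"],
  "properties": {
    "command": {"enum": ["fit", "test", "iterate", "simulate", "power"]},
    "alpha": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
    "t_upper": {"type": "number", "exclusiveMinimum": 0},
    "seed": {"type": "integer"},
    "config": {
      "type": "object",
      "required": ["hybrid", "parent1", "parent2", "outgroup"],
      "properties": {
        "hybrid": {"type": "string"},
        "parent1": {"type": "string"},
        "parent2": {"type": "string"},
        "outgroup": {"type": "string"},
        "t": {"type": "array", "items": {"type": "number", "minimum": 0},
              "minItems": 3, "maxItems": 3}
      }
    },
    "result": {
      "type": "object",
      "properties": {
        "gamma_hat": {"type": "number", "minimum": 0, "maximum": 1},
        "t_hat": {"type": "array", "items": {"type": "number", "minimum": 0},
                  "minItems": 3, "maxItems": 3},
        "lnL": {"type": "number"},
        "cycles_used": {"type": "integer", "minimum": 1},
        "converged": {"type": "boolean"},
        "boundary_flags": {"type": "object",
                           "additionalProperties": {"type": "boolean"}},
        "delta": {"type": "number", "minimum": 0},
        "p_value": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "full": {"type": "object"},
        "null": {"type": "object"}
      }
    },
    "rows": {"type": "array", "items": {"type": "object"}}
  }
}
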