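{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "nbroc strategy comparison report",
  "type": "object",
  "required": ["n", "prevalence", "n_mcnemar_tests", "strategies", "mcnemar"],
  "properties": {
    "n": {"type": "integer", "minimum": 1},
    "prevalence": {"type": "number", "minimum": 0, "maximum": 1},
    "n_mcnemar_tests": {"type": "integer", "minimum": 0},
    "strategies": {
      "type": "object",
      "minProperties": 1,
      "additionalProperties": {
        "type": "object",
        "required": ["threshold", "criterion_value", "se", "sp", "acc", "tp", "fp", "tn", "fn"],
        "properties": {
          "threshold": {"type": "number", "minimum": 0, "maximum": 1},
          "criterion_value": {"type": "number"},
          "se": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "sp": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "acc": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "tp": {"type": "integer", "minimum": 0},
          "fp": {"type": "integer", "minimum": 0},
          "tn": {"type": "integer", "minimum": 0},
          "fn": {"type": "integer", "minimum": 0}
        }
      }
    },
    "mcnemar": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["statistic", "p_value", "p_display", "method", "b", "c"],
        "properties": {
          "statistic": {"type": ["number", "null"], "minimum": 0},
          "p_value": {"type": "number", "minimum": 0, "maximum": 1},
          "p_display": {"type": "string"},
          "method": {"enum": ["exact_binomial", "chi_square_cc"]},
          "b": {"type": "integer", "minimum": 0},
          "c": {"type": "integer", "minimum": 0}
        }
      }
    }
  }
}
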