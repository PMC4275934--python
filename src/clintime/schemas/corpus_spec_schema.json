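{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://w3id.org/clintime/schemas/corpus_spec",
  "title": "Synthetic late-stent-thrombosis corpus specification",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "n_docs": {"type": "integer", "minimum": 0},
    "seed": {"type": "integer", "minimum": 0},
    "p_surgery": {"type": "number", "minimum": 0, "maximum": 1},
    "p_mi": {"type": "number", "minimum": 0, "maximum": 1},
    "p_er": {"type": "number", "minimum": 0, "maximum": 1},
    "p_death": {"type": "number", "minimum": 0, "maximum": 1},
    "therapy_duration_lognormal": {
      "type": "array",
      "items": {"type": "number"},
      "minItems": 2,
      "maxItems": 2,
      "description": "[mu, sigma] of log therapy duration in months"
    },
    "implant_to_lst_lognormal": {
      "type": "array",
      "items": {"type": "number"},
      "minItems": 2,
      "maxItems": 2,
      "description": "[mu, sigma] of log implant-to-thrombosis time in months"
    },
    "lst_group_effect": {
      "type": "number",
      "exclusiveMinimum": 0,
      "description": "multiplier on time-to-thrombosis when therapy lasted >= 6 months"
    },
    "expression_style_mix": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0},
      "description": "weights over absolute_day, absolute_month, offset_days, offset_months, explicit_duration; must sum to 1"
    },
    "p_missing_duration": {"type": "number", "minimum": 0, "maximum": 1},
    "p_range_duration": {"type": "number", "minimum": 0, "maximum": 1}
  }
}
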