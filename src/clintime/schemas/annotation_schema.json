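{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://w3id.org/clintime/schemas/annotation",
  "title": "Annotated clinical narrative document",
  "type": "object",
  "required": ["doc_id", "events", "assertions"],
  "additionalProperties": false,
  "properties": {
    "doc_id": {"type": "string", "minLength": 1},
    "narrative_text": {"type": "string"},
    "metadata": {"type": "object"},
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "event_type"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "event_type": {
            "type": "string",
            "enum": [
              "stent_implantation",
              "followup_stent_implantation",
              "antiplatelet_start",
              "antiplatelet_stop",
              "antiplatelet_therapy",
              "unrelated_surgery",
              "late_stent_thrombosis",
              "myocardial_infarction",
              "er_admission",
              "death",
              "other"
            ]
          },
          "label": {"type": "string"},
          "text_span": {
            "type": "array",
            "items": {"type": "integer", "minimum": 0},
            "minItems": 2,
            "maxItems": 2,
            "description": "0-based half-open character interval over narrative_text"
          }
        }
      }
    },
    "assertions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["subject", "relation", "object"],
        "additionalProperties": false,
        "properties": {
          "subject": {"type": "string"},
          "relation": {
            "type": "string",
            "enum": ["BEFORE", "AFTER", "EQUAL", "STARTS", "FINISHES", "CONTAINS", "DURING"]
          },
          "object": {
            "type": "object",
            "oneOf": [
              {"required": ["event"], "properties": {"event": {"type": "string"}}},
              {"required": ["time"], "properties": {"time": {"type": "string"}}}
            ]
          },
          "offset": {
            "type": "string",
            "description": "duration expression; only with BEFORE/AFTER"
          },
          "relation_granularity": {
            "type": "string",
            "enum": ["minute", "hour", "day", "month", "year"]
          },
          "asserted": {"type": "boolean", "default": true}
        }
      }
    },
    "timestamps": {
      "type": "object",
      "additionalProperties": {
        "oneOf": [
          {"type": "string"},
          {
            "type": "object",
            "additionalProperties": false,
            "properties": {
              "start": {"type": ["string", "null"]},
              "end": {"type": ["string", "null"]}
            }
          }
        ]
      },
      "description": "event id -> start (and optional end) time expressions"
    },
    "durations": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "event id -> duration expression"
    }
  }
}
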