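{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://w3id.org/clintime/schemas/gold",
  "title": "Gold-standard timeline and durations for one document",
  "type": "object",
  "required": ["doc_id", "ordered_events"],
  "additionalProperties": false,
  "properties": {
    "doc_id": {"type": "string", "minLength": 1},
    "ordered_events": {
      "type": "array",
      "items": {
        "type": "array",
        "items": {"type": "string"},
        "minItems": 1,
        "description": "one timeline bucket of simultaneous events, earliest bucket first"
      }
    },
    "event_durations": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "pair_durations": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "keys are 'earlierEventId|laterEventId'"
    }
  }
}
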