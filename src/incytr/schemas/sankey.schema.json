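{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Sankey export",
  "type": "object",
  "required": ["condition", "nodes", "links", "filters_applied"],
  "properties": {
    "condition": {"type": "string"},
    "sign_convention": {"type": "string"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "label", "role", "sender_group"],
        "properties": {
          "id": {"type": "integer"},
          "label": {"type": "string"},
          "role": {"type": "string"},
          "sender_group": {"type": "string"}
        }
      }
    },
    "links": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "weight"],
        "properties": {
          "source": {"type": "integer"},
          "target": {"type": "integer"},
          "weight": {"type": "integer"}
        }
      }
    },
    "filters_applied": {"type": "object"}
  }
}
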