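{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Cell-group interaction graph export",
  "type": "object",
  "required": ["condition", "nodes", "edges"],
  "properties": {
    "condition": {"type": "string"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["group", "n_cells"],
        "properties": {
          "group": {"type": "string"},
          "n_cells": {"type": "integer"}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["sender_group", "receiver_group", "n_pathways"],
        "properties": {
          "sender_group": {"type": "string"},
          "receiver_group": {"type": "string"},
          "n_pathways": {"type": "integer"}
        }
      }
    }
  }
}
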