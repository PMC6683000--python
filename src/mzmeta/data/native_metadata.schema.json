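{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/mzmeta/native_metadata.schema.json",
  "title": "Per-file acquisition metadata (native dialect)",
  "type": "object",
  "required": ["FileName", "Instruments"],
  "properties": {
    "FileName": {"type": "string", "minLength": 1},
    "AcquiredDate": {
      "type": ["string", "null"],
      "description": "ISO-8601 timestamp of acquisition start"
    },
    "SampleInfo": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "Instruments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["Model", "ModuleType"],
        "properties": {
          "Model": {"type": "string", "minLength": 1},
          "ModuleType": {"enum": ["MS", "LC", "OTHER"]},
          "MethodText": {"type": ["string", "null"]},
          "Parameters": {"$ref": "#/$defs/tree"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false,
  "$defs": {
    "tree": {
      "type": "object",
      "propertyNames": {"minLength": 1},
      "additionalProperties": {
        "anyOf": [
          {"type": ["string", "integer", "number", "boolean", "null"]},
          {"$ref": "#/$defs/tree"}
        ]
      }
    }
  }
}
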