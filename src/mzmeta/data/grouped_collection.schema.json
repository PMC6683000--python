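{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/mzmeta/grouped_collection.schema.json",
  "title": "Grouped collection: minimal parameter groups linked to file names",
  "type": "object",
  "required": ["Version", "Groups"],
  "properties": {
    "Version": {"type": "string"},
    "Groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["GroupId", "FileNames", "SharedParameters"],
        "properties": {
          "GroupId": {"type": "integer", "minimum": 1},
          "FileNames": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "minLength": 1},
            "uniqueItems": true
          },
          "SharedParameters": {
            "$ref": "native_metadata.schema.json#/$defs/tree"
          }
        },
        "additionalProperties": false
      }
    },
    "Failed": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["FileName", "Error"],
        "properties": {
          "FileName": {"type": "string"},
          "Error": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
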