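{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "mechsim/reaction.schema.json",
  "title": "Reaction collection",
  "description": "A collection of enzyme reaction records. Bond-change kinds: f (formed), c (cleaved), i (order increased), d (order decreased); 'involved' (stereochemistry change) is accepted on input in 'overall' only and is stripped.",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["id", "ec", "overall", "mechanism"],
    "additionalProperties": false,
    "properties": {
      "id": {"type": "string", "minLength": 1},
      "ec": {"type": "string", "pattern": "^[^.]+\\.[^.]+\\.[^.]+\\.[^.]+$"},
      "superfamilies": {"type": "array", "items": {"type": "string"}},
      "overall": {"$ref": "#/$defs/changeList"},
      "mechanism": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["index", "changes"],
          "additionalProperties": false,
          "properties": {
            "index": {"type": "integer", "minimum": 1},
            "spontaneous": {"type": "boolean", "default": false},
            "changes": {"$ref": "#/$defs/changeList"}
          }
        }
      },
      "permutation_allowed": {"type": "boolean", "default": false}
    }
  },
  "$defs": {
    "changeList": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "bond"],
        "additionalProperties": false,
        "properties": {
          "kind": {"enum": ["f", "c", "i", "d", "involved"]},
          "bond": {
            "type": "array",
            "items": {"type": "string", "minLength": 1, "maxLength": 2},
            "minItems": 2,
            "maxItems": 2
          }
        }
      }
    }
  }
}
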