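{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Per-paper binding-site annotation",
  "type": "object",
  "required": ["relevant"],
  "properties": {
    "doc_id": {"type": "string", "minLength": 1},
    "target_name": {"type": "string"},
    "relevant": {"type": "boolean"},
    "inconsistent": {"type": "boolean", "default": false},
    "pockets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "description", "residues"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "description": {"type": "string"},
          "residues": {
            "type": "array",
            "minItems": 1,
            "uniqueItems": true,
            "items": {
              "oneOf": [
                {
                  "type": "string",
                  "pattern": "^[A-Za-z0-9]{0,4}:[A-Za-z]{3}:-?[0-9]+[A-Za-z]?$",
                  "description": "Residue token CHAIN:RESNAME:RESID[ICODE], e.g. A:TYR:123"
                },
                {
                  "type": "object",
                  "required": ["name", "number"],
                  "properties": {
                    "chain": {"type": "string"},
                    "name": {"type": "string"},
                    "number": {"type": "integer"},
                    "icode": {"type": "string"}
                  }
                }
              ]
            }
          }
        }
      }
    }
  },
  "allOf": [
    {
      "if": {"properties": {"relevant": {"const": false}}},
      "then": {"properties": {"pockets": {"maxItems": 0}}}
    }
  ]
}
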