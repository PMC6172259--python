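{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "qalife counts file",
 "description": "Measurement counts for every element of an n-qubit basis. Keys of 'counts' must be exactly the 2^n bitstrings (zeros explicit); the leftmost bit belongs to the first role named in 'qubit_order'; 'shots' must equal the sum of all cells. Validation is performed by qalife.io (no jsonschema dependency).",
 "type": "object",
 "required": ["experiment", "basis", "qubit_order", "shots", "counts"],
 "properties": {
  "experiment": {"type": "string"},
  "basis": {"enum": ["z", "x"]},
  "qubit_order": {"type": "string", "pattern": "^(g|p)[0-9]((g|p)[0-9])*$"},
  "shots": {"type": "integer", "minimum": 1},
  "counts": {
   "type": "object",
   "patternProperties": {"^[01]+$": {"type": "integer", "minimum": 0}},
   "additionalProperties": false
  },
  "provenance": {"type": "string"}
 }
}
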