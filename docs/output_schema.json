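{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pepikit --json output",
  "description": "Shape of the document every pepikit subcommand emits with --json. 'results' mirrors the analysis result: estimates carry point/scale/method/flags/intervals, test results carry statistic/df/p_value/sidedness/method/flags; infinities are encoded as the strings 'inf'/'-inf' and NaN as null.",
  "type": "object",
  "required": ["schema_version", "command", "inputs", "results"],
  "properties": {
    "schema_version": {"type": "integer", "const": 1},
    "command": {"type": "string"},
    "inputs": {"type": "object"},
    "results": {"type": "object"}
  },
  "additionalProperties": false
}
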