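{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "haplopower run record",
  "type": "object",
  "required": [
    "command",
    "params",
    "seed",
    "result",
    "elapsed_s",
    "timestamp",
    "software_version"
  ],
  "properties": {
    "command": {"type": "string"},
    "params": {"type": "object"},
    "seed": {"type": ["integer", "null"]},
    "result": {"type": "object"},
    "elapsed_s": {"type": "number"},
    "timestamp": {"type": "string"},
    "software_version": {"type": "string"}
  }
}
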