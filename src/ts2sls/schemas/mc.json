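{
  "type": "object",
  "required": ["reps", "seed", "n1", "n2", "kz", "kx", "true_beta",
               "methods", "warnings"],
  "properties": {
    "reps": {"type": "integer"},
    "seed": {"type": "integer"},
    "n1": {"type": "integer"},
    "n2": {"type": "integer"},
    "kz": {"type": "integer"},
    "kx": {"type": "integer"},
    "true_beta": {"type": "array", "items": {"type": "number"}},
    "methods": {"type": "object"},
    "warnings": {"type": "array", "items": {"type": "string"}}
  }
}
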