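{
  "type": "object",
  "required": ["estimator", "vcov_method", "n1", "n2", "kz", "kx",
               "exposures", "beta_hat", "se", "ci95_lower", "ci95_upper",
               "first_stage_F"],
  "properties": {
    "estimator": {"type": "string"},
    "vcov_method": {"type": "string"},
    "n1": {"type": "integer"},
    "n2": {"type": "integer"},
    "kz": {"type": "integer"},
    "kx": {"type": "integer"},
    "exposures": {"type": "array", "items": {"type": "string"}},
    "beta_hat": {"type": "array", "items": {"type": "number"}},
    "se": {"type": "array", "items": {"type": "number"}},
    "ci95_lower": {"type": "array", "items": {"type": "number"}},
    "ci95_upper": {"type": "array", "items": {"type": "number"}},
    "first_stage_F": {"type": "array", "items": {"type": "number"}}
  }
}
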