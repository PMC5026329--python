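{
  "type": "object",
  "required": ["estimator", "n1", "n2", "kz", "kx", "beta_hat", "se",
               "J", "J_df", "J_pvalue", "converged", "iterations"],
  "properties": {
    "estimator": {"type": "string"},
    "n1": {"type": "integer"},
    "n2": {"type": "integer"},
    "kz": {"type": "integer"},
    "kx": {"type": "integer"},
    "beta_hat": {"type": "array", "items": {"type": "number"}},
    "se": {"type": "array", "items": {"type": "number"}},
    "J": {"type": "number"},
    "J_df": {"type": "integer"},
    "J_pvalue": {"type": ["number", "null"]},
    "converged": {"type": "boolean"},
    "iterations": {"type": "integer"}
  }
}
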