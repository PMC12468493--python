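{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "covuniform run report",
  "type": "object",
  "required": ["config", "version", "groups", "rankings", "outputs", "checksums"],
  "properties": {
    "config": {"type": "object"},
    "version": {"type": "string"},
    "outputs": {"type": "object"},
    "checksums": {"type": "object"},
    "rankings": {
      "type": "object",
      "required": ["by_fwhm", "by_r_squared"],
      "properties": {
        "by_fwhm": {"type": "array", "items": {"type": "string"}},
        "by_r_squared": {"type": "array", "items": {"type": "string"}}
      }
    },
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["library", "sample", "replicates", "uniformity"],
        "properties": {
          "library": {"type": "string"},
          "sample": {"type": "string"},
          "replicates": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["replicate", "seed", "bias_score", "mean_depth"],
              "properties": {
                "replicate": {"type": "string"},
                "seed": {"type": "integer"},
                "bias_score": {"type": "number"},
                "mean_depth": {"type": "number"}
              }
            }
          },
          "uniformity": {
            "type": "object",
            "required": ["slope", "intercept", "r_squared", "fwhm", "bandwidth", "n_genes"],
            "properties": {
              "slope": {"type": "number"},
              "intercept": {"type": "number"},
              "r_squared": {"type": "number"},
              "fwhm": {"type": "number"},
              "bandwidth": {"type": "number"},
              "n_genes": {"type": "integer"}
            }
          }
        }
      }
    }
  }
}
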