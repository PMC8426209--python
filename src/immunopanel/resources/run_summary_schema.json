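{
  "title": "immunopanel run summary",
  "type": "object",
  "required": [
    "package_version", "seed", "parameter_hash", "stages",
    "n_samples", "n_genes", "n_hot", "n_cold",
    "n_omnibus_significant", "venn_up", "venn_down",
    "cluster_association_p", "warnings"
  ],
  "properties": {
    "package_version": {"type": "string"},
    "seed": {"type": "integer"},
    "parameter_hash": {"type": "string"},
    "stages": {"type": "object"},
    "n_samples": {"type": "integer"},
    "n_genes": {"type": "integer"},
    "n_hot": {"type": "integer"},
    "n_cold": {"type": "integer"},
    "n_omnibus_significant": {"type": "integer"},
    "venn_up": {"type": "object"},
    "venn_down": {"type": "object"},
    "cluster_association_p": {"type": "number"},
    "warnings": {"type": "array"}
  }
}
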