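{
  "type": "object",
  "required": ["seed", "config", "conditions", "comparisons", "models"],
  "properties": {
    "seed": {"type": "integer"},
    "config": {"type": "object", "required": ["alpha", "min_total", "permutations", "uniformity_replicates"]},
    "conditions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "species", "temperature", "n_tested", "n_hi", "n_complete_lethal",
          "minimal_locus_count", "component_count", "mean_v_hat", "sd_v_hat",
          "uniformity"
        ],
        "properties": {
          "species": {"type": "string"},
          "temperature": {"type": "string"},
          "n_tested": {"type": "integer"},
          "n_hi": {"type": "integer"},
          "n_complete_lethal": {"type": "integer"},
          "minimal_locus_count": {"type": "integer"},
          "component_count": {"type": "integer"},
          "mean_v_hat": {"type": "number"},
          "sd_v_hat": {"type": "number"},
          "uniformity": {"type": "object"}
        }
      }
    },
    "comparisons": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "species", "n_universe", "n_a", "n_b", "n_both", "n_only_a",
          "n_only_b", "p_randomization", "p_hypergeometric", "permutations"
        ]
      }
    },
    "models": {
      "type": "object",
      "required": ["paired_t", "anova_two_way", "cell_model_4", "anova_three_way", "cell_model_12", "contrasts"]
    }
  }
}
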