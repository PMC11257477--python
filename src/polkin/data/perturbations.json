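{
  "comment": "Catalog of published rate perturbations mimicking conditional depletion/inactivation experiments. Cells are either point overrides (s^-1) or re-fitted free-rate ranges; blank rates stay at their baseline values. 'context' selects the baseline fit whose fixed rates and free-rate ranges apply.",
  "contexts": {
    "standard": {
      "fixed": {"k1": 0.002, "k_minus1": 0.003, "k3": 0.002, "k5": 0.1, "k6_speed": 1000.0, "k7": 0.037},
      "free_ranges": {"k2": [0.03, 0.2], "k_minus2": [0.0, 0.15], "k_minus3": [0.0, 0.03], "k4": [0.0075, 0.09]}
    },
    "gcn4": {
      "fixed": {"k1": 0.002, "k_minus1": 0.003, "k5": 0.1, "k6_speed": 1000.0, "k7": 0.0614},
      "free_ranges": {"k2": [0.03, 0.2], "k_minus2": [0.0, 0.04], "k_minus3": [0.0, 0.03], "k4": [0.01, 0.15]}
    }
  },
  "experiments": [
    {"experiment": "sua7_degradation", "gene_class": "STM", "model": 1, "context": "standard",
     "description": "↓k2",
     "changes": {"k2": {"range": [0.004, 0.04]}}},
    {"experiment": "sua7_degradation", "gene_class": "STM", "model": 2, "context": "standard",
     "description": "↓k2+↑k−1",
     "changes": {"k_minus1": {"override": 0.04}, "k2": {"range": [0.004, 0.04]}}},
    {"experiment": "sua7_degradation", "gene_class": "STM", "model": 3, "context": "standard",
     "description": "↓k2+↓k1",
     "changes": {"k1": {"override": 0.0006}, "k2": {"range": [0.004, 0.04]}}},
    {"experiment": "sua7_degradation", "gene_class": "TFO", "model": 1, "context": "standard",
     "description": "↓k3",
     "changes": {"k3": {"override": 0.0008}}},
    {"experiment": "sua7_degradation", "gene_class": "TFO", "model": 2, "context": "standard",
     "description": "↓k3+↑k−3",
     "changes": {"k3": {"override": 0.0008}, "k_minus3": {"range": [0.0, 0.12]}}},
    {"experiment": "kin28_inhibition", "gene_class": "STM", "model": 1, "context": "standard",
     "description": "↓k5",
     "changes": {"k5": {"override": 0.02}}},
    {"experiment": "kin28_inhibition", "gene_class": "STM", "model": 2, "context": "standard",
     "description": "↓k5+↑k−3",
     "changes": {"k_minus3": {"range": [0.0, 0.24]}, "k5": {"override": 0.02}}},
    {"experiment": "kin28_inhibition", "gene_class": "STM", "model": 3, "context": "standard",
     "description": "↓k5+↑k−1",
     "changes": {"k_minus1": {"override": 0.06}, "k5": {"override": 0.02}}},
    {"experiment": "kin28_inhibition", "gene_class": "STM", "model": 4, "context": "standard",
     "description": "↓k5+↓k1",
     "changes": {"k1": {"override": 0.0005}, "k5": {"override": 0.02}}},
    {"experiment": "kin28_inhibition", "gene_class": "TFO", "model": 1, "context": "standard",
     "description": "↓k5",
     "changes": {"k5": {"override": 0.02}}},
    {"experiment": "kin28_inhibition", "gene_class": "TFO", "model": 2, "context": "standard",
     "description": "↓k5+↑k−3",
     "changes": {"k_minus3": {"range": [0.0, 0.24]}, "k5": {"override": 0.02}}},
    {"experiment": "kin28_inhibition", "gene_class": "TFO", "model": 3, "context": "standard",
     "description": "↓k5+↓k3",
     "changes": {"k3": {"override": 0.0005}, "k5": {"override": 0.02}}},
    {"experiment": "gcn4_pd", "gene_class": "STM", "model": 1, "context": "gcn4",
     "description": "↑k−3",
     "changes": {"k_minus3": {"range": [0.0, 0.048]}}},
    {"experiment": "gcn4_pd", "gene_class": "STM", "model": 2, "context": "gcn4",
     "description": "↓k2+↑k−3",
     "changes": {"k2": {"range": [0.0092, 0.092]}, "k_minus3": {"range": [0.0, 0.045]}}},
    {"experiment": "gcn4_null", "gene_class": "STM", "model": 1, "context": "gcn4",
     "description": "↓k1",
     "changes": {"k1": {"override": 0.0006}}}
  ]
}
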