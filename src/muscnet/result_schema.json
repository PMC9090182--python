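{
  "type": "object",
  "required": ["provenance", "duets"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["config_hash", "versions"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": ["integer", "null"]},
        "versions": {
          "type": "object",
          "required": ["muscnet", "numpy", "scipy", "sklearn"],
          "properties": {
            "muscnet": {"type": "string"},
            "numpy": {"type": "string"},
            "scipy": {"type": "string"},
            "sklearn": {"type": "string"}
          }
        }
      }
    },
    "duets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["pair"],
        "properties": {
          "pair": {"type": "array", "items": {"type": "string"}},
          "alpha_table": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["config", "predictions", "confusion", "metrics", "per_fold_selected"],
              "properties": {
                "config": {"type": "object"},
                "predictions": {"type": "array", "items": {"type": "integer"}},
                "scores": {"type": "array", "items": {"type": "number"}},
                "confusion": {
                  "type": "object",
                  "required": ["TP", "FN", "TN", "FP"],
                  "properties": {
                    "TP": {"type": "integer"},
                    "FN": {"type": "integer"},
                    "TN": {"type": "integer"},
                    "FP": {"type": "integer"}
                  }
                },
                "metrics": {
                  "type": "object",
                  "required": ["Acc", "Sn", "Sp"],
                  "properties": {
                    "Acc": {"type": "number"},
                    "Sn": {"type": "number"},
                    "Sp": {"type": "number"}
                  }
                },
                "per_fold_selected": {"type": "array", "items": {"type": "object"}},
                "fallback_folds": {"type": "integer"}
              }
            }
          },
          "best": {"type": "object"},
          "nested": {"type": "object"}
        }
      }
    }
  }
}
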