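{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "segnav run configuration",
  "description": "Validated by segnav.pipeline.RunConfig (pydantic). Exactly one of 'simulation' or 'inputs' must be present.",
  "type": "object",
  "required": ["seed"],
  "properties": {
    "seed": {
      "type": "integer",
      "description": "Run-level seed, split deterministically into per-stage substreams."
    },
    "simulation": {
      "type": "object",
      "description": "Generate all pipeline inputs with known ground truth.",
      "properties": {
        "n_subjects": {"type": "integer", "minimum": 1, "default": 40},
        "network_sizes": {
          "type": "array", "items": {"type": "integer", "minimum": 2},
          "default": [15, 15, 15, 15],
          "description": "Parcels per network; singletons have no within edges."
        },
        "n_timepoints": {"type": "integer", "minimum": 3, "default": 250},
        "r_within": {"type": "number", "default": 0.5},
        "r_between": {"type": "number", "default": 0.1,
                      "description": "Must satisfy 0 <= r_between < r_within < 1."},
        "ar1": {"type": "number", "minimum": 0, "exclusiveMaximum": 1, "default": 0},
        "gm_contamination_slope": {"type": "number", "default": 0},
        "carrier_fraction": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.3},
        "subtasks": {
          "type": "array",
          "items": {"enum": ["PPI", "BPI", "LPI"]},
          "default": ["PPI", "LPI"]
        },
        "n_trials_per_subtask": {"type": "integer", "minimum": 1, "default": 12},
        "beta_homa": {"type": "number", "default": 0},
        "beta_seg": {"type": "number", "default": 0},
        "beta_homa_x_seg": {"type": "number", "default": 0},
        "beta_apoe": {"type": "number", "default": 0}
      }
    },
    "inputs": {
      "type": "object",
      "description": "Paths to real parcel-level input tables.",
      "required": ["series_manifest", "parcellation", "phenotypes", "trials"],
      "properties": {
        "series_manifest": {"type": "string"},
        "parcellation": {"type": "string"},
        "phenotypes": {"type": "string"},
        "trials": {"type": "string"},
        "gm_thickness": {"type": "string"},
        "gm_myelin": {"type": "string"}
      }
    },
    "variants": {
      "type": "array",
      "items": {"enum": ["raw", "partial_thickness", "partial_myelin"]},
      "default": ["raw"]
    },
    "class_map": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "network label -> class (e.g. sensorimotor / associative)."
    },
    "ladder": {
      "enum": ["apoe_homa_subtask", "homa_moderation", "apoe_moderation", "none"],
      "default": "homa_moderation"
    },
    "log_level": {"type": "string", "default": "INFO"}
  }
}
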