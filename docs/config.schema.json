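{
  "$defs": {
    "CleaningSettings": {
      "properties": {
        "gap_ms": {
          "default": 100.0,
          "title": "Gap Ms",
          "type": "number"
        },
        "outlier_cm": {
          "default": 15.0,
          "title": "Outlier Cm",
          "type": "number"
        },
        "smoothing_ms": {
          "default": 100.0,
          "title": "Smoothing Ms",
          "type": "number"
        },
        "anticipatory_window_s": {
          "default": 2.25,
          "title": "Anticipatory Window S",
          "type": "number"
        },
        "reactive_window_s": {
          "default": 3.5,
          "title": "Reactive Window S",
          "type": "number"
        }
      },
      "title": "CleaningSettings",
      "type": "object"
    },
    "ObserverSettings": {
      "description": "Population of simulated observers (device units).",
      "properties": {
        "base_threshold_mean": {
          "default": 5.0,
          "title": "Base Threshold Mean",
          "type": "number"
        },
        "base_threshold_sd": {
          "default": 1.2,
          "title": "Base Threshold Sd",
          "type": "number"
        },
        "min_threshold": {
          "default": 2.5,
          "title": "Min Threshold",
          "type": "number"
        },
        "track_jitter_sd": {
          "default": 0.75,
          "title": "Track Jitter Sd",
          "type": "number"
        },
        "interval_offsets": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Interval Offsets",
          "type": "object"
        },
        "condition_offsets": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Condition Offsets",
          "type": "object"
        }
      },
      "title": "ObserverSettings",
      "type": "object"
    },
    "QuestSettings": {
      "properties": {
        "beta": {
          "default": 3.5,
          "title": "Beta",
          "type": "number"
        },
        "gamma": {
          "default": 0.01,
          "title": "Gamma",
          "type": "number"
        },
        "delta": {
          "default": 0.01,
          "title": "Delta",
          "type": "number"
        },
        "intensity_scale": {
          "default": "log10",
          "title": "Intensity Scale",
          "type": "string"
        },
        "prior_mean": {
          "default": 5.0,
          "title": "Prior Mean",
          "type": "number"
        },
        "prior_sd": {
          "default": 1.5,
          "title": "Prior Sd",
          "type": "number"
        },
        "block_prior_sd": {
          "default": 0.5,
          "title": "Block Prior Sd",
          "type": "number"
        },
        "grid_points": {
          "default": 201,
          "minimum": 100,
          "title": "Grid Points",
          "type": "integer"
        },
        "grid_span_sd": {
          "default": 5.0,
          "minimum": 4.0,
          "title": "Grid Span Sd",
          "type": "number"
        },
        "intensity_min": {
          "default": 1,
          "title": "Intensity Min",
          "type": "integer"
        },
        "intensity_max": {
          "default": 200,
          "title": "Intensity Max",
          "type": "integer"
        }
      },
      "title": "QuestSettings",
      "type": "object"
    },
    "StatSettings": {
      "properties": {
        "iqr_multiplier": {
          "default": 3.5,
          "title": "Iqr Multiplier",
          "type": "number"
        },
        "alpha": {
          "default": 0.05,
          "title": "Alpha",
          "type": "number"
        }
      },
      "title": "StatSettings",
      "type": "object"
    },
    "SwaySettings": {
      "properties": {
        "theta": {
          "default": 1.0,
          "title": "Theta",
          "type": "number"
        },
        "cop_sd_m": {
          "default": 0.005,
          "title": "Cop Sd M",
          "type": "number"
        },
        "head_sd_m": {
          "default": 0.003,
          "title": "Head Sd M",
          "type": "number"
        },
        "anticipatory_damping": {
          "default": 0.5,
          "title": "Anticipatory Damping",
          "type": "number"
        },
        "cop_reactive_m": {
          "default": 0.02,
          "title": "Cop Reactive M",
          "type": "number"
        },
        "head_reactive_m": {
          "default": 0.01,
          "title": "Head Reactive M",
          "type": "number"
        },
        "gap_rate": {
          "default": 0.0,
          "title": "Gap Rate",
          "type": "number"
        },
        "outlier_rate": {
          "default": 0.0,
          "title": "Outlier Rate",
          "type": "number"
        }
      },
      "title": "SwaySettings",
      "type": "object"
    }
  },
  "description": "Full experiment/analysis configuration.",
  "properties": {
    "design": {
      "default": "exp1",
      "title": "Design",
      "type": "string"
    },
    "n_subjects": {
      "default": 20,
      "minimum": 1,
      "title": "N Subjects",
      "type": "integer"
    },
    "quest": {
      "$ref": "#/$defs/QuestSettings"
    },
    "cleaning": {
      "$ref": "#/$defs/CleaningSettings"
    },
    "observers": {
      "$ref": "#/$defs/ObserverSettings"
    },
    "sway": {
      "$ref": "#/$defs/SwaySettings"
    },
    "stats": {
      "$ref": "#/$defs/StatSettings"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "with_kinematics": {
      "default": true,
      "title": "With Kinematics",
      "type": "boolean"
    }
  },
  "title": "AnalysisConfig",
  "type": "object"
}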