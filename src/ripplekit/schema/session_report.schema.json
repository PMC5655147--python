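{
 "$defs": {
  "AnalysisConfig": {
   "description": "Every knob the pipeline uses; embedded verbatim in reports.",
   "properties": {
    "coupling": {
     "$ref": "#/$defs/CouplingSettings"
    },
    "delta": {
     "additionalProperties": true,
     "title": "Delta",
     "type": "object"
    },
    "ripple": {
     "additionalProperties": true,
     "title": "Ripple",
     "type": "object"
    },
    "seed": {
     "default": 0,
     "title": "Seed",
     "type": "integer"
    },
    "spindle": {
     "additionalProperties": true,
     "title": "Spindle",
     "type": "object"
    },
    "staging_lfp_role": {
     "default": "CA1_LFP",
     "title": "Staging Lfp Role",
     "type": "string"
    }
   },
   "title": "AnalysisConfig",
   "type": "object"
  },
  "ArchitectureModel": {
   "properties": {
    "mean_nrem_epoch_s": {
     "title": "Mean Nrem Epoch S",
     "type": "number"
    },
    "n_nrem_epochs": {
     "title": "N Nrem Epochs",
     "type": "integer"
    },
    "total_nrem_s": {
     "title": "Total Nrem S",
     "type": "number"
    },
    "total_rem_s": {
     "title": "Total Rem S",
     "type": "number"
    },
    "total_wake_s": {
     "title": "Total Wake S",
     "type": "number"
    }
   },
   "required": [
    "total_nrem_s",
    "mean_nrem_epoch_s",
    "n_nrem_epochs",
    "total_rem_s",
    "total_wake_s"
   ],
   "title": "ArchitectureModel",
   "type": "object"
  },
  "CorrelogramSummary": {
   "properties": {
    "n_skipped": {
     "default": 0,
     "title": "N Skipped",
     "type": "integer"
    },
    "n_windows": {
     "title": "N Windows",
     "type": "integer"
    },
    "peak_coef": {
     "title": "Peak Coef",
     "type": "number"
    },
    "peak_lag_s": {
     "title": "Peak Lag S",
     "type": "number"
    }
   },
   "required": [
    "peak_coef",
    "peak_lag_s",
    "n_windows"
   ],
   "title": "CorrelogramSummary",
   "type": "object"
  },
  "CouplingSettings": {
   "properties": {
    "half_window_s": {
     "default": 4.0,
     "title": "Half Window S",
     "type": "number"
    },
    "joint_window_s": {
     "default": 0.25,
     "title": "Joint Window S",
     "type": "number"
    },
    "n_shuffles": {
     "default": 100,
     "title": "N Shuffles",
     "type": "integer"
    },
    "peak_search_s": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": 0.5,
     "title": "Peak Search S"
    },
    "shift_range_s": {
     "default": [
      4.0,
      null
     ],
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "anyOf": [
        {
         "type": "number"
        },
        {
         "type": "null"
        }
       ]
      }
     ],
     "title": "Shift Range S",
     "type": "array"
    },
    "shuffle_mode": {
     "default": "global",
     "title": "Shuffle Mode",
     "type": "string"
    },
    "step_s": {
     "default": 0.01,
     "title": "Step S",
     "type": "number"
    },
    "ts_bin_s": {
     "default": 0.1,
     "title": "Ts Bin S",
     "type": "number"
    }
   },
   "title": "CouplingSettings",
   "type": "object"
  },
  "CouplingSummary": {
   "properties": {
    "amp_null_pct99": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Amp Null Pct99"
    },
    "amp_xcorr": {
     "anyOf": [
      {
       "$ref": "#/$defs/CorrelogramSummary"
      },
      {
       "type": "null"
      }
     ],
     "default": null
    },
    "is_significant": {
     "anyOf": [
      {
       "type": "boolean"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Is Significant"
    },
    "joint_rate": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Joint Rate"
    },
    "ripple_delta_xcorr": {
     "anyOf": [
      {
       "$ref": "#/$defs/CorrelogramSummary"
      },
      {
       "type": "null"
      }
     ],
     "default": null
    },
    "ts_xcorr": {
     "anyOf": [
      {
       "$ref": "#/$defs/CorrelogramSummary"
      },
      {
       "type": "null"
      }
     ],
     "default": null
    }
   },
   "title": "CouplingSummary",
   "type": "object"
  },
  "EventSummary": {
   "properties": {
    "count": {
     "title": "Count",
     "type": "integer"
    },
    "incidence_per_min_nrem": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Incidence Per Min Nrem"
    },
    "mean_peak_amp": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Mean Peak Amp"
    }
   },
   "required": [
    "count"
   ],
   "title": "EventSummary",
   "type": "object"
  }
 },
 "properties": {
  "architecture": {
   "anyOf": [
    {
     "$ref": "#/$defs/ArchitectureModel"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "band_power": {
   "additionalProperties": {
    "additionalProperties": {
     "type": "number"
    },
    "type": "object"
   },
   "title": "Band Power",
   "type": "object"
  },
  "coupling": {
   "$ref": "#/$defs/CouplingSummary"
  },
  "delta": {
   "anyOf": [
    {
     "$ref": "#/$defs/EventSummary"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "null_reasons": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Null Reasons",
   "type": "object"
  },
  "params": {
   "$ref": "#/$defs/AnalysisConfig"
  },
  "recording_id": {
   "title": "Recording Id",
   "type": "string"
  },
  "ripple": {
   "anyOf": [
    {
     "$ref": "#/$defs/EventSummary"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "spindle": {
   "anyOf": [
    {
     "$ref": "#/$defs/EventSummary"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "warnings": {
   "items": {
    "type": "string"
   },
   "title": "Warnings",
   "type": "array"
  }
 },
 "required": [
  "recording_id",
  "seed",
  "params"
 ],
 "title": "SessionReport",
 "type": "object"
}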