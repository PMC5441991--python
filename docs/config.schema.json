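{
 "$defs": {
  "JitterConfig": {
   "properties": {
    "gain_sd_db": {
     "default": 1.5,
     "minimum": 0,
     "title": "Gain Sd Db",
     "type": "number"
    },
    "phase_sd_deg": {
     "default": 15.0,
     "minimum": 0,
     "title": "Phase Sd Deg",
     "type": "number"
    },
    "contra_slope_sd_deg_per_khz": {
     "default": 8.0,
     "minimum": 0,
     "title": "Contra Slope Sd Deg Per Khz",
     "type": "number"
    }
   },
   "title": "JitterConfig",
   "type": "object"
  },
  "ObserverConfig": {
   "properties": {
    "level_step_db": {
     "default": 0.2,
     "title": "Level Step Db",
     "type": "number"
    },
    "phase_step_deg": {
     "default": 2.0,
     "title": "Phase Step Deg",
     "type": "number"
    },
    "level_noise_db": {
     "default": 0.4,
     "title": "Level Noise Db",
     "type": "number"
    },
    "phase_noise_deg": {
     "default": 4.0,
     "title": "Phase Noise Deg",
     "type": "number"
    },
    "n_refinement_iters": {
     "default": 2,
     "title": "N Refinement Iters",
     "type": "integer"
    },
    "grade_thresholds_db": {
     "default": [
      3.0,
      12.0,
      25.0,
      40.0
     ],
     "maxItems": 4,
     "minItems": 4,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Grade Thresholds Db",
     "type": "array"
    },
    "lf_noise_factor": {
     "default": 5.0,
     "title": "Lf Noise Factor",
     "type": "number"
    },
    "lf_cutoff_hz": {
     "default": 1000.0,
     "title": "Lf Cutoff Hz",
     "type": "number"
    },
    "lf_decay_hz": {
     "default": 2500.0,
     "title": "Lf Decay Hz",
     "type": "number"
    },
    "hf_corner_hz": {
     "default": 7000.0,
     "title": "Hf Corner Hz",
     "type": "number"
    },
    "hf_rise_per_khz": {
     "default": 0.3,
     "title": "Hf Rise Per Khz",
     "type": "number"
    }
   },
   "title": "ObserverConfig",
   "type": "object"
  }
 },
 "description": "Full configuration of one simulated participant run.",
 "properties": {
  "experiment": {
   "enum": [
    "exp1",
    "exp2"
   ],
   "title": "Experiment",
   "type": "string"
  },
  "model_seed": {
   "default": 1,
   "title": "Model Seed",
   "type": "integer"
  },
  "run_seed": {
   "default": 1,
   "title": "Run Seed",
   "type": "integer"
  },
  "n_sessions": {
   "default": 8,
   "title": "N Sessions",
   "type": "integer"
  },
  "observer": {
   "$ref": "#/$defs/ObserverConfig",
   "default": {
    "level_step_db": 0.2,
    "phase_step_deg": 2.0,
    "level_noise_db": 0.4,
    "phase_noise_deg": 4.0,
    "n_refinement_iters": 2,
    "grade_thresholds_db": [
     3.0,
     12.0,
     25.0,
     40.0
    ],
    "lf_noise_factor": 5.0,
    "lf_cutoff_hz": 1000.0,
    "lf_decay_hz": 2500.0,
    "hf_corner_hz": 7000.0,
    "hf_rise_per_khz": 0.3
   }
  },
  "jitter": {
   "$ref": "#/$defs/JitterConfig",
   "default": {
    "gain_sd_db": 1.5,
    "phase_sd_deg": 15.0,
    "contra_slope_sd_deg_per_khz": 8.0
   }
  },
  "anchor_freq_hz": {
   "default": 250.0,
   "title": "Anchor Freq Hz",
   "type": "number"
  }
 },
 "required": [
  "experiment"
 ],
 "title": "ExperimentConfig",
 "type": "object"
}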