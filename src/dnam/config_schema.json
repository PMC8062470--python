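{
 "$defs": {
  "ClusterConfig": {
   "additionalProperties": false,
   "properties": {
    "band_frac": {
     "default": 0.15,
     "maximum": 1,
     "minimum": 0,
     "title": "Band Frac",
     "type": "number"
    },
    "min_count": {
     "default": 50,
     "minimum": 1,
     "title": "Min Count",
     "type": "integer"
    },
    "radius_nm": {
     "default": 60.0,
     "exclusiveMinimum": 0,
     "title": "Radius Nm",
     "type": "number"
    }
   },
   "title": "ClusterConfig",
   "type": "object"
  },
  "CodecConfig": {
   "additionalProperties": false,
   "properties": {
    "max_expansions": {
     "default": 10000,
     "minimum": 1,
     "title": "Max Expansions",
     "type": "integer"
    },
    "max_flips": {
     "default": 9,
     "minimum": 0,
     "title": "Max Flips",
     "type": "integer"
    },
    "n_droplets": {
     "default": 15,
     "minimum": 1,
     "title": "N Droplets",
     "type": "integer"
    },
    "redundancy": {
     "default": 1.5,
     "exclusiveMinimum": 0,
     "title": "Redundancy",
     "type": "number"
    },
    "segment_bits": {
     "default": 16,
     "minimum": 1,
     "title": "Segment Bits",
     "type": "integer"
    }
   },
   "title": "CodecConfig",
   "type": "object"
  },
  "FitConfig": {
   "additionalProperties": false,
   "properties": {
    "gtol": {
     "default": 1e-06,
     "exclusiveMinimum": 0,
     "title": "Gtol",
     "type": "number"
    },
    "max_iter": {
     "default": 300,
     "minimum": 1,
     "title": "Max Iter",
     "type": "integer"
    },
    "pitch_nm": {
     "default": 10.0,
     "exclusiveMinimum": 0,
     "title": "Pitch Nm",
     "type": "number"
    }
   },
   "title": "FitConfig",
   "type": "object"
  },
  "SimulatorConfig": {
   "additionalProperties": false,
   "properties": {
    "copies_per_origami": {
     "default": 10,
     "minimum": 1,
     "title": "Copies Per Origami",
     "type": "integer"
    },
    "error_means": {
     "items": {
      "type": "number"
     },
     "title": "Error Means",
     "type": "array"
    },
    "message_sizes": {
     "items": {
      "type": "integer"
     },
     "title": "Message Sizes",
     "type": "array"
    },
    "repetitions": {
     "default": 40,
     "minimum": 1,
     "title": "Repetitions",
     "type": "integer"
    }
   },
   "title": "SimulatorConfig",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "Top-level configuration; unknown keys are rejected.",
 "properties": {
  "cluster": {
   "$ref": "#/$defs/ClusterConfig"
  },
  "codec": {
   "$ref": "#/$defs/CodecConfig"
  },
  "fit": {
   "$ref": "#/$defs/FitConfig"
  },
  "layout_path": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Layout Path"
  },
  "schema_version": {
   "default": 1,
   "title": "Schema Version",
   "type": "integer"
  },
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  },
  "simulator": {
   "$ref": "#/$defs/SimulatorConfig"
  }
 },
 "title": "RunConfig",
 "type": "object"
}
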