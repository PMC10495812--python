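{
  "$defs": {
    "UnitDecision": {
      "description": "Outcome of the conservation-unit rule for a two-group comparison.",
      "properties": {
        "esu_indeterminate": {
          "title": "Esu Indeterminate",
          "type": "boolean"
        },
        "max_migration": {
          "title": "Max Migration",
          "type": "number"
        },
        "migration_below_threshold": {
          "title": "Migration Below Threshold",
          "type": "boolean"
        },
        "n_ESU": {
          "minimum": 1,
          "title": "N Esu",
          "type": "integer"
        },
        "n_MU": {
          "minimum": 1,
          "title": "N Mu",
          "type": "integer"
        },
        "nuclear_divergence_significant": {
          "title": "Nuclear Divergence Significant",
          "type": "boolean"
        },
        "nuclear_p": {
          "title": "Nuclear P",
          "type": "number"
        },
        "plastid_reciprocal_monophyly_spatial": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "title": "Plastid Reciprocal Monophyly Spatial"
        },
        "rationale": {
          "items": {
            "type": "string"
          },
          "title": "Rationale",
          "type": "array"
        }
      },
      "required": [
        "n_ESU",
        "n_MU",
        "nuclear_divergence_significant",
        "nuclear_p",
        "migration_below_threshold",
        "max_migration",
        "plastid_reciprocal_monophyly_spatial",
        "esu_indeterminate",
        "rationale"
      ],
      "title": "UnitDecision",
      "type": "object"
    }
  },
  "description": "Schema of the JSON report written by :func:`run_pipeline`.",
  "properties": {
    "abc": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "title": "Abc"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "cpdna": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "title": "Cpdna"
    },
    "failures": {
      "items": {
        "type": "string"
      },
      "title": "Failures",
      "type": "array"
    },
    "log": {
      "items": {
        "type": "string"
      },
      "title": "Log",
      "type": "array"
    },
    "nuclear": {
      "additionalProperties": true,
      "title": "Nuclear",
      "type": "object"
    },
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "units": {
      "anyOf": [
        {
          "$ref": "#/$defs/UnitDecision"
        },
        {
          "type": "null"
        }
      ]
    }
  },
  "required": [
    "package_version",
    "seed",
    "config",
    "nuclear",
    "cpdna",
    "abc",
    "units",
    "failures",
    "log"
  ],
  "title": "PipelineReport",
  "type": "object"
}
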