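{
  "$defs": {
    "NeutralFitReport": {
      "properties": {
        "N": {
          "title": "N",
          "type": "number"
        },
        "band_method": {
          "title": "Band Method",
          "type": "string"
        },
        "d": {
          "title": "D",
          "type": "number"
        },
        "m_hat": {
          "title": "M Hat",
          "type": "number"
        },
        "n_above": {
          "title": "N Above",
          "type": "integer"
        },
        "n_absent_in_source": {
          "title": "N Absent In Source",
          "type": "integer"
        },
        "n_below": {
          "title": "N Below",
          "type": "integer"
        },
        "n_consistent": {
          "title": "N Consistent",
          "type": "integer"
        },
        "n_otus": {
          "title": "N Otus",
          "type": "integer"
        },
        "n_subjects": {
          "title": "N Subjects",
          "type": "integer"
        },
        "source": {
          "title": "Source",
          "type": "string"
        },
        "sse": {
          "title": "Sse",
          "type": "number"
        },
        "table_used": {
          "title": "Table Used",
          "type": "string"
        }
      },
      "required": [
        "source",
        "m_hat",
        "sse",
        "n_subjects",
        "N",
        "d",
        "n_otus",
        "n_consistent",
        "n_above",
        "n_below",
        "n_absent_in_source",
        "table_used",
        "band_method"
      ],
      "title": "NeutralFitReport",
      "type": "object"
    },
    "PairedPermutationReport": {
      "properties": {
        "mode": {
          "title": "Mode",
          "type": "string"
        },
        "n_permutations": {
          "title": "N Permutations",
          "type": "integer"
        },
        "observed": {
          "title": "Observed",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        }
      },
      "required": [
        "observed",
        "p_value",
        "n_permutations",
        "mode"
      ],
      "title": "PairedPermutationReport",
      "type": "object"
    },
    "PermanovaReport": {
      "properties": {
        "n_permutations": {
          "title": "N Permutations",
          "type": "integer"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "pseudo_F": {
          "title": "Pseudo F",
          "type": "number"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        }
      },
      "required": [
        "pseudo_F",
        "r_squared",
        "p_value",
        "n_permutations",
        "seed"
      ],
      "title": "PermanovaReport",
      "type": "object"
    },
    "StageLogEntry": {
      "properties": {
        "duration_s": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Duration S"
        },
        "input_shape": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "integer"
                },
                {
                  "type": "integer"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Input Shape"
        },
        "message": {
          "default": "",
          "title": "Message",
          "type": "string"
        },
        "output_shape": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "integer"
                },
                {
                  "type": "integer"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Output Shape"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        },
        "stage": {
          "title": "Stage",
          "type": "string"
        }
      },
      "required": [
        "stage"
      ],
      "title": "StageLogEntry",
      "type": "object"
    },
    "SummaryStats": {
      "properties": {
        "mean": {
          "title": "Mean",
          "type": "number"
        },
        "median": {
          "title": "Median",
          "type": "number"
        },
        "n_samples": {
          "title": "N Samples",
          "type": "integer"
        },
        "total": {
          "title": "Total",
          "type": "integer"
        }
      },
      "required": [
        "n_samples",
        "total",
        "mean",
        "median"
      ],
      "title": "SummaryStats",
      "type": "object"
    }
  },
  "properties": {
    "alpha_diversity": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Alpha Diversity",
      "type": "array"
    },
    "alpha_pairwise": {
      "additionalProperties": {
        "items": {
          "additionalProperties": true,
          "type": "object"
        },
        "type": "array"
      },
      "title": "Alpha Pairwise",
      "type": "object"
    },
    "depth_summary_subjects": {
      "$ref": "#/$defs/SummaryStats"
    },
    "depth_summary_with_controls": {
      "$ref": "#/$defs/SummaryStats"
    },
    "dropped_samples": {
      "items": {
        "type": "string"
      },
      "title": "Dropped Samples",
      "type": "array"
    },
    "neutral_fits": {
      "items": {
        "$ref": "#/$defs/NeutralFitReport"
      },
      "title": "Neutral Fits",
      "type": "array"
    },
    "paired_permutation": {
      "$ref": "#/$defs/PairedPermutationReport"
    },
    "pcoa_proportion_explained": {
      "items": {
        "type": "number"
      },
      "title": "Pcoa Proportion Explained",
      "type": "array"
    },
    "permanova_site": {
      "$ref": "#/$defs/PermanovaReport"
    },
    "permanova_subject": {
      "anyOf": [
        {
          "$ref": "#/$defs/PermanovaReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "rarefaction_depth": {
      "title": "Rarefaction Depth",
      "type": "integer"
    },
    "removed_contaminants": {
      "items": {
        "type": "string"
      },
      "title": "Removed Contaminants",
      "type": "array"
    },
    "stage_log": {
      "items": {
        "$ref": "#/$defs/StageLogEntry"
      },
      "title": "Stage Log",
      "type": "array"
    }
  },
  "required": [
    "depth_summary_subjects",
    "depth_summary_with_controls",
    "removed_contaminants",
    "rarefaction_depth",
    "dropped_samples",
    "alpha_diversity",
    "alpha_pairwise",
    "pcoa_proportion_explained",
    "permanova_site",
    "paired_permutation",
    "neutral_fits",
    "stage_log"
  ],
  "title": "PipelineReport",
  "type": "object"
}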