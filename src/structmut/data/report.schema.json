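{
  "$defs": {
    "AnalysisEntry": {
      "additionalProperties": false,
      "properties": {
        "analysis": {
          "title": "Analysis",
          "type": "string"
        },
        "applicable": {
          "title": "Applicable",
          "type": "boolean"
        },
        "flagged": {
          "title": "Flagged",
          "type": "boolean"
        },
        "score": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Score"
        },
        "units": {
          "title": "Units",
          "type": "string"
        },
        "detail": {
          "title": "Detail",
          "type": "string"
        },
        "threshold": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Threshold"
        },
        "threshold_source": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "title": "Threshold Source"
        },
        "extras": {
          "additionalProperties": true,
          "title": "Extras",
          "type": "object"
        }
      },
      "required": [
        "analysis",
        "applicable",
        "flagged",
        "score",
        "units",
        "detail",
        "threshold",
        "threshold_source",
        "extras"
      ],
      "title": "AnalysisEntry",
      "type": "object"
    },
    "MutationBlock": {
      "additionalProperties": false,
      "properties": {
        "structure": {
          "title": "Structure",
          "type": "string"
        },
        "chain": {
          "title": "Chain",
          "type": "string"
        },
        "resnum": {
          "title": "Resnum",
          "type": "integer"
        },
        "insert_code": {
          "title": "Insert Code",
          "type": "string"
        },
        "native": {
          "title": "Native",
          "type": "string"
        },
        "mutant": {
          "title": "Mutant",
          "type": "string"
        },
        "mutation_key": {
          "title": "Mutation Key",
          "type": "string"
        }
      },
      "required": [
        "structure",
        "chain",
        "resnum",
        "insert_code",
        "native",
        "mutant",
        "mutation_key"
      ],
      "title": "MutationBlock",
      "type": "object"
    },
    "SummaryBlock": {
      "additionalProperties": false,
      "properties": {
        "flags": {
          "additionalProperties": true,
          "title": "Flags",
          "type": "object"
        },
        "explained": {
          "title": "Explained",
          "type": "boolean"
        }
      },
      "required": [
        "flags",
        "explained"
      ],
      "title": "SummaryBlock",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "schema_version": {
      "title": "Schema Version",
      "type": "string"
    },
    "mutation": {
      "$ref": "#/$defs/MutationBlock"
    },
    "summary": {
      "$ref": "#/$defs/SummaryBlock"
    },
    "detail": {
      "items": {
        "$ref": "#/$defs/AnalysisEntry"
      },
      "title": "Detail",
      "type": "array"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    }
  },
  "required": [
    "schema_version",
    "mutation",
    "summary",
    "detail",
    "parameters"
  ],
  "title": "ReportModel",
  "type": "object"
}
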