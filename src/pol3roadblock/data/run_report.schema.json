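{
  "properties": {
    "artifacts": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Artifacts",
      "type": "object"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "stage_counts": {
      "additionalProperties": {
        "anyOf": [
          {
            "type": "integer"
          },
          {
            "type": "null"
          }
        ]
      },
      "title": "Stage Counts",
      "type": "object"
    },
    "stages_skipped": {
      "items": {
        "type": "string"
      },
      "title": "Stages Skipped",
      "type": "array"
    },
    "track_seeds": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Track Seeds",
      "type": "object"
    },
    "version": {
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "version",
    "seed",
    "parameters",
    "stage_counts",
    "stages_skipped",
    "artifacts"
  ],
  "title": "RunReport",
  "type": "object"
}
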