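{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/dynatrack/registry.schema.json",
  "title": "dynatrack registry configuration",
  "description": "Declares static tracks, dependent track sets (signal + companion feature dataset) and track groups. Data paths are resolved relative to the configuration file. This document is the reference for the configuration dialect; runtime validation is performed by the datamodel module.",
  "type": "object",
  "additionalProperties": false,
  "required": ["track_sets", "groups"],
  "properties": {
    "static_tracks": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "path", "position"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "path": {"type": "string", "minLength": 1},
          "position": {"type": "integer", "minimum": 0}
        }
      }
    },
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "mode": {
            "enum": ["automatic", "manual", "disabled"],
            "default": "automatic"
          },
          "anchor": {
            "type": "string",
            "minLength": 1,
            "description": "Id of a static track or another group below which this group's block is always placed. The anchor relation must be acyclic."
          },
          "max_visible": {"type": "integer", "minimum": 1}
        }
      }
    },
    "track_sets": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "signal_path", "feature_path", "group_id", "rank"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "signal_path": {"type": "string", "minLength": 1},
          "feature_path": {"type": "string", "minLength": 1},
          "group_id": {"type": "string", "minLength": 1},
          "rank": {
            "type": "integer",
            "minimum": 0,
            "description": "Display rank within the owning group; unique per group."
          }
        }
      }
    },
    "global_max_visible": {
      "type": "integer",
      "minimum": 1,
      "description": "Upper bound on group-managed visible tracks across all groups; static tracks are not counted. Absent means unlimited."
    }
  }
}
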