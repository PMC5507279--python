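{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rpsim run summary",
  "type": "object",
  "required": ["config_toml", "seed", "outcome", "final_step", "wall_steps",
               "stabilization_step", "final_counts", "events"],
  "properties": {
    "config_toml": {"type": "string"},
    "seed": {"type": "integer"},
    "outcome": {
      "type": "string",
      "enum": ["survived", "extinct_parasites", "extinct_replicases",
               "extinct_both"]
    },
    "final_step": {"type": "integer"},
    "wall_steps": {"type": "integer"},
    "stabilization_step": {"type": "object"},
    "final_counts": {
      "type": "object",
      "required": ["replicases", "parasites"],
      "properties": {
        "replicases": {"type": "integer"},
        "parasites": {"type": "integer"}
      }
    },
    "events": {
      "type": "object",
      "required": ["decays_free", "decays_in_complex", "dissociations",
                   "replications", "complex_formations",
                   "overcrowd_removals", "overcrowd_molecules"]
    }
  }
}
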