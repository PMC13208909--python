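{
  "title": "riskconcord run report",
  "description": "Top-level structure of report.json; enforced by riskconcord.pipeline.validate_report.",
  "required": {
    "manifest": ["str"],
    "policies": ["list"],
    "eligibility": ["list"],
    "agreement": ["dict"],
    "consensus": ["dict"],
    "scoring_failures": ["int"]
  }
}
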