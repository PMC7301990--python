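{
  "indicator_merges": [
    {
      "sources": ["process-convenience", "operational-ease-of-use"],
      "target": {
        "id": "operational-convenience",
        "name": "Operational Convenience",
        "dimension_id": "system-quality"
      }
    },
    {
      "sources": ["doctor-patient-ratio", "consultation-visitors"],
      "target": {
        "id": "rationality-of-doctor-patient-ratio",
        "name": "Rationality of Doctor-Patient Ratio",
        "dimension_id": "structure-quality"
      }
    },
    {
      "sources": ["treatment-effect", "re-consultation-rate"],
      "target": {
        "id": "treatment-effect",
        "name": "Treatment Effect",
        "dimension_id": "outcome-quality"
      }
    }
  ],
  "dimension_merges": [
    {
      "sources": ["network-quality", "system-quality"],
      "target": {"id": "system-quality", "name": "System Quality"}
    }
  ]
}
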