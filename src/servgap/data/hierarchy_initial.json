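{
  "dimensions": [
    {"id": "network-quality", "name": "Network Quality"},
    {"id": "system-quality", "name": "System Quality"},
    {"id": "structure-quality", "name": "Structure Quality"},
    {"id": "interaction-quality", "name": "Interaction Quality"},
    {"id": "outcome-quality", "name": "Outcome Quality"}
  ],
  "indicators": [
    {"id": "network-service-provider", "name": "Network Service Provider", "dimension_id": "network-quality"},
    {"id": "network-rate", "name": "Network Rate", "dimension_id": "network-quality"},
    {"id": "video-resolution", "name": "Video Resolution", "dimension_id": "system-quality"},
    {"id": "equipment-quality", "name": "Equipment Quality", "dimension_id": "system-quality"},
    {"id": "process-convenience", "name": "Process Convenience", "dimension_id": "system-quality"},
    {"id": "operational-ease-of-use", "name": "Operational Ease of Use", "dimension_id": "system-quality"},
    {"id": "doctor-patient-ratio", "name": "Doctor-Patient Ratio", "dimension_id": "structure-quality"},
    {"id": "consultation-visitors", "name": "Consultation Visitors", "dimension_id": "structure-quality"},
    {"id": "turnover-rates", "name": "Turnover Rates of Consulting Room", "dimension_id": "structure-quality"},
    {"id": "charges", "name": "Charges", "dimension_id": "structure-quality"},
    {"id": "purpose-of-application", "name": "Purpose of Application", "dimension_id": "interaction-quality"},
    {"id": "appointment-channel", "name": "Appointment Channel", "dimension_id": "interaction-quality"},
    {"id": "waiting-time", "name": "Waiting Time", "dimension_id": "interaction-quality"},
    {"id": "regional-hospital-level", "name": "Regional Hospital Level", "dimension_id": "interaction-quality"},
    {"id": "data-integrity", "name": "Data Integrity", "dimension_id": "interaction-quality"},
    {"id": "regional-doctor-level", "name": "Regional Doctor Level", "dimension_id": "interaction-quality"},
    {"id": "expert-level", "name": "Expert Level", "dimension_id": "interaction-quality"},
    {"id": "operators-attitude", "name": "Operators' Attitude", "dimension_id": "interaction-quality"},
    {"id": "experts-attitude", "name": "Experts' Attitude", "dimension_id": "interaction-quality"},
    {"id": "consultation-duration", "name": "Consultation Duration", "dimension_id": "interaction-quality"},
    {"id": "information-usefulness", "name": "Information Usefulness", "dimension_id": "outcome-quality"},
    {"id": "diagnostic-coincidence-rate", "name": "Diagnostic Coincidence Rate", "dimension_id": "outcome-quality"},
    {"id": "treatment-effect", "name": "Treatment Effect", "dimension_id": "outcome-quality"},
    {"id": "re-consultation-rate", "name": "Re-consultation Rate", "dimension_id": "outcome-quality"}
  ]
}
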