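indicator_id,name,a,b,c,d
network-service-provider,Network Service Provider,0.206,0.301,0.431,0.527
network-rate,Network Rate,0.512,0.607,0.713,0.808
video-resolution,Video Resolution,0.608,0.703,0.823,0.896
equipment-quality,Equipment Quality,0.648,0.743,0.848,0.914
process-convenience,Process Convenience,0.412,0.507,0.602,0.697
operational-ease-of-use,Operational Ease of Use,0.392,0.487,0.582,0.677
doctor-patient-ratio,Doctor-Patient Ratio,0.573,0.668,0.773,0.861
consultation-visitors,Consultation Visitors,0.432,0.528,0.623,0.718
turnover-rates,Turnover Rates of Consulting Room,0.558,0.653,0.758,0.846
charges,Charges,0.563,0.659,0.764,0.852
purpose-of-application,Purpose of Application,0.573,0.668,0.798,0.879
appointment-channel,Appointment Channel,0.226,0.321,0.462,0.557
waiting-time,Waiting Time,0.578,0.673,0.794,0.874
regional-hospital-level,Regional Hospital Level,0.643,0.738,0.864,0.932
data-integrity,Data Integrity,0.533,0.628,0.733,0.828
regional-doctor-level,Regional Doctor Level,0.568,0.663,0.758,0.854
expert-level,Expert Level,0.810,0.905,1.000,1.000
operators-attitude,Operators' Attitude,0.568,0.663,0.758,0.854
experts-attitude,Experts' Attitude,0.618,0.713,0.829,0.909
consultation-duration,Consultation Duration,0.533,0.628,0.723,0.811
information-usefulness,Information Usefulness,0.649,0.744,0.839,0.915
diagnostic-coincidence-rate,Diagnostic Coincidence Rate,0.668,0.764,0.859,0.919
treatment-effect,Treatment Effect,0.810,0.905,1.000,1.000
re-consultation-rate,Re-consultation Rate,0.427,0.522,0.617,0.712
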