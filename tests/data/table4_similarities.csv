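indicator_id,s0,s1,s2,s3,s4,s5,s6,argmax_term
network-service-provider,0.6916,0.8264,0.9641,0.8661,0.7126,0.5586,0.4239,2
network-rate,0.3976,0.5324,0.6864,0.8399,0.9768,0.8526,0.7179,4
video-resolution,0.3001,0.4348,0.5888,0.7423,0.8958,0.9502,0.8154,5
equipment-quality,0.2695,0.4042,0.5582,0.7117,0.8652,0.9796,0.8461,5
process-convenience,0.5030,0.6378,0.7918,0.9453,0.9012,0.7472,0.6125,3
operational-ease-of-use,0.5235,0.6582,0.8122,0.9657,0.8808,0.7268,0.5920,3
doctor-patient-ratio,0.3391,0.4739,0.6279,0.7814,0.9349,0.9112,0.7764,4
consultation-visitors,0.4826,0.6173,0.7713,0.9248,0.9217,0.7677,0.6330,3
turnover-rates,0.3539,0.4887,0.6427,0.7962,0.9497,0.8964,0.7616,4
charges,0.3482,0.4830,0.6370,0.7905,0.9440,0.9020,0.7673,4
purpose-of-application,0.3284,0.4631,0.6171,0.7706,0.9241,0.9219,0.7871,4
appointment-channel,0.6660,0.8007,0.9523,0.8918,0.7383,0.5843,0.4495,2
waiting-time,0.3279,0.4626,0.6166,0.7701,0.9236,0.9224,0.7877,4
regional-hospital-level,0.2632,0.3979,0.5519,0.7054,0.8589,0.9733,0.8524,5
data-integrity,0.3771,0.5119,0.6659,0.8194,0.9703,0.8731,0.7384,4
regional-doctor-level,0.3469,0.4817,0.6357,0.7892,0.9427,0.9033,0.7686,4
expert-level,0.1291,0.2639,0.4179,0.5714,0.7249,0.8789,0.9864,6
operators-attitude,0.3469,0.4817,0.6357,0.7892,0.9427,0.9033,0.7686,4
experts-attitude,0.2902,0.4250,0.5790,0.7325,0.8860,0.9600,0.8253,5
consultation-duration,0.3841,0.5189,0.6729,0.8264,0.9773,0.8661,0.7314,4
information-usefulness,0.2710,0.4057,0.5597,0.7132,0.8667,0.9793,0.8445,5
diagnostic-coincidence-rate,0.2553,0.3901,0.5441,0.6976,0.8511,0.9886,0.8602,5
treatment-effect,0.1291,0.2639,0.4179,0.5714,0.7249,0.8789,0.9864,6
re-consultation-rate,0.4882,0.6229,0.7769,0.9304,0.9161,0.7621,0.6273,3
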