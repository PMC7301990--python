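code,indicator_id,dimension_code,name,name_source,ap_a,ap_b,ap_c,ap_d,ae_a,ae_b,ae_c,ae_d,p,e,gap
C_11,network-rate,C_1,Network Rate,text,0.612,0.689,0.766,0.843,0.614,0.691,0.768,0.845,0.728,0.730,-0.002
C_12,video-resolution,C_1,Video Resolution,text,0.619,0.696,0.773,0.850,0.615,0.692,0.769,0.846,0.735,0.731,0.004
C_13,equipment-quality,C_1,Equipment Quality,text,0.611,0.688,0.765,0.842,0.610,0.687,0.763,0.840,0.727,0.725,0.002
C_14,operational-convenience,C_1,Operational Convenience,text,0.587,0.664,0.741,0.818,0.605,0.682,0.758,0.835,0.715,0.720,-0.005
C_21,rationality-of-doctor-patient-ratio,C_2,Rationality of Doctor-Patient Ratio,positional,0.604,0.681,0.758,0.835,0.605,0.682,0.758,0.835,0.720,0.720,-0.001
C_22,turnover-rates,C_2,Turnover Rates of Consulting Room,text,0.560,0.637,0.713,0.790,0.590,0.667,0.744,0.821,0.675,0.706,-0.031
C_23,charges,C_2,Charges,text,0.578,0.655,0.732,0.809,0.604,0.681,0.757,0.834,0.694,0.719,-0.026
C_31,purpose-of-application,C_3,Purpose of Application,positional,0.599,0.676,0.753,0.830,0.594,0.671,0.748,0.825,0.715,0.710,0.005
C_32,waiting-time,C_3,Waiting Time,positional,0.609,0.686,0.763,0.840,0.614,0.691,0.768,0.845,0.725,0.730,-0.005
C_33,regional-hospital-level,C_3,Regional Hospital Level,positional,0.585,0.662,0.739,0.816,0.581,0.658,0.734,0.811,0.701,0.696,0.004
C_34,data-integrity,C_3,Data Integrity,positional,0.622,0.699,0.776,0.853,0.616,0.693,0.770,0.847,0.738,0.732,0.006
C_35,regional-doctor-level,C_3,Regional Doctor Level,positional,0.593,0.670,0.747,0.824,0.612,0.689,0.766,0.843,0.709,0.728,-0.019
C_36,expert-level,C_3,Expert Level,positional,0.643,0.720,0.797,0.874,0.631,0.708,0.785,0.862,0.759,0.747,0.012
C_37,operators-attitude,C_3,Operators' Attitude,text,0.590,0.666,0.743,0.819,0.620,0.697,0.774,0.851,0.705,0.736,-0.031
C_38,experts-attitude,C_3,Experts' Attitude,text,0.590,0.667,0.744,0.821,0.615,0.692,0.769,0.846,0.706,0.731,-0.025
C_39,consultation-duration,C_3,Consultation Duration,text,0.537,0.614,0.691,0.768,0.569,0.646,0.723,0.780,0.653,0.681,-0.029
C_41,information-usefulness,C_4,Information Usefulness,positional,0.626,0.703,0.780,0.857,0.589,0.666,0.743,0.820,0.742,0.705,0.037
C_42,diagnostic-coincidence-rate,C_4,Diagnostic Coincidence Rate,positional,0.627,0.704,0.781,0.858,0.591,0.668,0.745,0.822,0.743,0.707,0.036
C_43,treatment-effect,C_4,Treatment Effect,positional,0.626,0.703,0.780,0.857,0.600,0.677,0.754,0.831,0.742,0.716,0.026
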