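code,dimension_id,name,ap_a,ap_b,ap_c,ap_d,ae_a,ae_b,ae_c,ae_d,p,e,gap
C_1,system-quality,System Quality,0.607,0.684,0.761,0.838,0.611,0.688,0.765,0.842,0.723,0.727,-0.004
C_2,structure-quality,Structure Quality,0.581,0.658,0.734,0.811,0.600,0.677,0.753,0.830,0.696,0.715,-0.019
C_3,interaction-quality,Interaction Quality,0.598,0.675,0.752,0.829,0.604,0.681,0.758,0.833,0.714,0.719,-0.005
C_4,outcome-quality,Outcome Quality,0.590,0.667,0.743,0.820,0.595,0.672,0.749,0.826,0.705,0.711,-0.006
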