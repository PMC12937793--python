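sigma,dP_rest_mmHg,FFR_rest,FFR_rest_clamped,dP_hyper_mmHg,FFR_hyper,FFR_hyper_clamped,dP_rest_sigfigs,dP_hyper_sigfigs,hyper_unit_suspect
0.00,0.40,0.996,0,1.19,0.988,0,2,2,0
0.25,0.76,0.992,0,3.18,0.968,0,2,2,0
0.50,12.91,0.871,0,107.47,0.0,1,4,5,0
0.75,4600.0,0.0,1,5510000.0,0.0,1,3,3,1
0.90,7800000.0,0.0,1,9360000000.0,0.0,1,3,3,1
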