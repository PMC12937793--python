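label,n,stenosis_note,psvr_note,PSV_mps,PSV_sd,dP_clin_mmHg,dP_clin_sd,dP_clin_censored,ABI,ABI_sd,dU_V,dU_sd,dP_eq_mmHg,dP_eq_sd
normal,3,<20%,PSVR < 1.5,0.9,0.2,1.0,0.5,<2,1.06,0.04,0.0,0.0,0.0,0.0
mild,4,20-30%,PSVR ~ 2.0,1.5,0.3,3.0,1.0,,0.92,0.05,0.5,0.1,4.0,1.0
moderate,5,40-60%,PSVR ~ 3.0,2.3,0.4,11.0,2.0,,0.80,0.07,1.2,0.2,10.0,2.0
severe,5,70-80%,PSVR ~ 4.5,3.5,0.6,24.0,5.0,,0.59,0.09,2.8,0.3,24.0,3.0
critical,3,>90%,PSVR > 6.0,4.9,0.7,46.0,6.0,,0.41,0.08,5.4,0.4,43.0,5.0
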