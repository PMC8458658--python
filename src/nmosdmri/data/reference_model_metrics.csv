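model,tp,fp,tn,fn,tp_rate,fp_rate,precision,f_measure,roc_area
Paty,29,9,91,33,0.637,0.259,0.752,0.669,0.689
Swanton,48,43,57,14,0.696,0.352,0.633,0.642,0.672
Matthews/Jurynczyk/Hyun,34,25,75,28,0.626,0.324,0.634,0.630,0.649
Liao,5,0,100,57,0.432,4.352,0.861,0.390,0.540
Bensi,33,24,76,29,0.619,0.327,0.634,0.626,0.646
NMO/MS score,53,9,91,9,0.876,0.111,0.876,0.876,0.882
Machine learning algorithm,52,9,91,10,0.866,0.117,0.871,0.868,0.874
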