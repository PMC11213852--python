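cluster,n,improved,improved_pct,no_change,no_change_pct,deteriorated,deteriorated_pct,dead,dead_pct,not_reassessed,not_reassessed_pct,lost,lost_pct
musculoskeletal_sensory,618,115,18.6,214,34.6,126,20.4,121,19.6,39,6.3,3,0.5
cardiac,412,71,17.2,116,28.2,96,23.3,112,27.2,17,4.1,0,0.0
neurological,459,60,13.1,167,36.4,144,31.4,74,16.1,13,2.8,1,0.2
respiratory_cancer,244,28,11.5,49,20.1,44,18.0,113,46.3,10,4.1,0,0.0
insulin_dependent_diabetes,214,42,19.6,62,29.0,35,16.4,58,27.1,15,7.0,2,0.9
unspecified,799,87,10.9,273,34.2,277,34.7,125,15.6,33,4.1,4,0.5
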