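taxon,muscle,inlever_mm,fbite_anterior_N,fbite_mid_palate_N,fbite_posterior_N,contribution_pct
Incisivosaurus,mAMEM,19.8,6.0,7.5,9.3,11.3
Incisivosaurus,mAMEP,30.3,8.2,10.3,12.7,15.4
Incisivosaurus,mAMES,23.4,11.4,14.4,17.8,21.6
Incisivosaurus,mAMP,19.9,5.4,6.8,8.4,10.2
Incisivosaurus,mPSTp,26.0,2.8,3.6,4.4,5.3
Incisivosaurus,mPSTs,31.5,4.5,5.7,7.0,8.5
Incisivosaurus,mPTd,9.4,1.3,1.6,2.0,2.5
Incisivosaurus,mPTv,17.6,13.5,17.0,20.9,25.4
Citipati,mAMEM,37.1,47.1,54.9,67.4,13.5
Citipati,mAMEP,61.9,54.2,63.1,77.5,15.5
Citipati,mAMES,48.0,94.4,109.9,134.9,27.0
Citipati,mAMP,47.2,33.1,38.5,47.2,9.5
Citipati,mPSTp,56.8,25.2,29.3,36.0,7.2
Citipati,mPSTs,66.7,39.7,46.2,56.7,11.4
Citipati,mPTd,18.1,7.3,8.5,10.5,2.1
Citipati,mPTv,30.6,48.2,56.1,68.8,13.8
Khaan,mAMEM,18.6,11.8,13.7,16.9,8.6
Khaan,mAMEP,34.3,23.2,27.0,33.3,16.9
Khaan,mAMES,27.4,30.8,36.0,44.3,22.4
Khaan,mAMP,26.1,11.1,12.9,15.9,8.1
Khaan,mPSTp,36.5,9.4,10.9,13.5,6.8
Khaan,mPSTs,41.4,14.7,17.1,21.1,10.7
Khaan,mPTd,13.4,4.3,5.0,6.1,3.1
Khaan,mPTv,24.7,32.3,37.7,46.5,23.5
Conchoraptor,mAMEM,16.8,7.2,8.0,10.6,6.7
Conchoraptor,mAMEP,29.8,17.2,19.2,25.3,16.1
Conchoraptor,mAMES,24.7,21.5,24.0,31.6,20.2
Conchoraptor,mAMP,21.1,11.3,12.6,16.6,10.6
Conchoraptor,mPSTp,26.5,6.6,7.4,9.7,6.2
Conchoraptor,mPSTs,31.6,10.8,12.0,15.9,10.1
Conchoraptor,mPTd,13.6,3.5,4.0,5.2,3.3
Conchoraptor,mPTv,22.1,28.6,31.9,42.0,26.8
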